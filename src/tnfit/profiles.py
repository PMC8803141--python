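"""Per-sample insertion profiles: (position, strand) -> read count.

The profile is the central exchange object between the simulator, the read
processor and the per-gene summaries. Site uniqueness is strand-aware by
default; :meth:`InsertionProfile.collapse_strands` merges the two
orientations when a position-only convention is wanted.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

SITE_TABLE_COLUMNS = ("replicon", "position", "strand", "read_count")


@dataclass
class InsertionProfile:
    sample_id: str
    replicon_id: str
    counts: dict[tuple[int, str], int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for (pos, strand), c in self.counts.items():
            if c <= 0:
                raise ValueError(f"zero/negative count stored at ({pos},{strand})")
            if pos < 1:
                raise ValueError(f"position {pos} is not 1-based")
            if strand not in ("+", "-"):
                raise ValueError(f"bad strand {strand!r}")

    @property
    def total_reads(self) -> int:
        return int(sum(self.counts.values()))

    @property
    def n_sites(self) -> int:
        return len(self.counts)

    def sorted_sites(self) -> list[tuple[int, str]]:
        return sorted(self.counts)

    def arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Deterministically ordered (positions, strands, counts) arrays."""
        sites = self.sorted_sites()
        pos = np.array([p for p, _ in sites], dtype=np.int64)
        strand = np.array([s for _, s in sites], dtype="U1")
        cnt = np.array([self.counts[s] for s in sites], dtype=np.int64)
        return pos, strand, cnt

    def collapse_strands(self) -> "InsertionProfile":
        merged: dict[tuple[int, str], int] = {}
        for (pos, _), c in self.counts.items():
            key = (pos, "+")
            merged[key] = merged.get(key, 0) + c
        return InsertionProfile(self.sample_id, self.replicon_id, merged)

    # ------------------------------------------------------------------ I/O

    def to_frame(self) -> pd.DataFrame:
        pos, strand, cnt = self.arrays()
        return pd.DataFrame(
            {
                "replicon": self.replicon_id,
                "position": pos,
                "strand": strand,
                "read_count": cnt,
            }
        )

    def write_tsv(self, path: str | os.PathLike) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path: str | os.PathLike, sample_id: str | None = None) -> "InsertionProfile":
        df = pd.read_csv(path, sep="\t", dtype={"strand": str})
        missing = set(SITE_TABLE_COLUMNS) - set(df.columns)
        if missing:
            raise ValueError(f"site table missing columns: {sorted(missing)}")
        if df.empty:
            raise ValueError("empty site table has no replicon id; pass one explicitly")
        replicon = str(df["replicon"].iloc[0])
        counts = {
            (int(r.position), str(r.strand)): int(r.read_count)
            for r in df.itertuples()
        }
        name = sample_id if sample_id is not None else os.path.splitext(os.path.basename(path))[0]
        return cls(sample_id=name, replicon_id=replicon, counts=counts)
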