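"""Per-gene insertion summaries: counts, insertion index, density, replicate agreement.

The insertion index of a gene is its number of unique insertion sites
divided by its length in bp; genes intolerant of insertion (essential under
the sampled condition) sit near zero while freely disrupted genes sit near
the genome-wide density. Replicate agreement is quantified as the Pearson
correlation of per-gene insertion indices, the same quantity plotted when
comparing biological replicates of a library.
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import stats as sps

from .genome import AnnotatedGenome
from .profiles import InsertionProfile

GENE_TABLE_COLUMNS = (
    "gene_id",
    "length_bp",
    "unique_insertions",
    "read_count",
    "insertion_index",
)


@dataclass(frozen=True)
class GeneInsertionStats:
    gene_id: str
    length_bp: int
    unique_insertions: int
    read_count: int
    insertion_index: float


@dataclass(frozen=True)
class CorrelationReport:
    n_genes: int
    pearson_r: float
    r_squared: float

    def write_json(self, path: str | os.PathLike) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)
            fh.write("\n")


def insertion_index(unique_insertions: int, length_bp: int) -> float:
    """Unique insertion sites per bp of gene."""
    if length_bp < 1:
        raise ValueError("length_bp must be >= 1")
    if unique_insertions < 0:
        raise ValueError("unique_insertions must be >= 0")
    return unique_insertions / length_bp


def genome_density(n_unique_sites: int, genome_length_bp: int) -> float:
    """Genome-wide density as bp per unique insertion site."""
    if n_unique_sites < 1:
        raise ValueError("need at least one unique site to define a density")
    return genome_length_bp / n_unique_sites


def summarize_genes(
    profile: InsertionProfile,
    genome: AnnotatedGenome,
    end_trim_fraction: float = 0.0,
) -> list[GeneInsertionStats]:
    """Per-gene unique sites, read counts and insertion index.

    A site at (pos, strand) is credited to gene g iff pos lies within g's
    coordinates after symmetrically trimming ``floor(end_trim_fraction *
    length)`` bp from each end (insertion tolerance at gene ends is common,
    so the window is configurable; default no trimming). Sites are credited
    to every covering gene if genes overlap; intergenic sites are ignored.
    Unique sites are strand-aware unless the profile was strand-collapsed.
    """
    if not 0.0 <= end_trim_fraction < 0.5:
        raise ValueError("end_trim_fraction must be in [0, 0.5)")
    pos, _, cnt = profile.arrays()
    out: list[GeneInsertionStats] = []
    for g in genome.genes:
        trim = math.floor(end_trim_fraction * g.length_bp)
        lo, hi = g.start + trim, g.end - trim
        i0, i1 = np.searchsorted(pos, (lo, hi + 1))
        unique = int(i1 - i0)
        reads = int(cnt[i0:i1].sum())
        out.append(
            GeneInsertionStats(
                gene_id=g.gene_id,
                length_bp=g.length_bp,
                unique_insertions=unique,
                read_count=reads,
                insertion_index=insertion_index(unique, g.length_bp),
            )
        )
    return out


def gene_stats_frame(stats: list[GeneInsertionStats]) -> pd.DataFrame:
    return pd.DataFrame([asdict(s) for s in stats], columns=list(GENE_TABLE_COLUMNS))


def write_gene_stats(stats: list[GeneInsertionStats], path: str | os.PathLike) -> None:
    gene_stats_frame(stats).to_csv(path, sep="\t", index=False)


def read_gene_stats(path: str | os.PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(GENE_TABLE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"gene table missing columns: {sorted(missing)}")
    return df


def replicate_correlation(
    stats_a: list[GeneInsertionStats], stats_b: list[GeneInsertionStats]
) -> CorrelationReport:
    """Pearson correlation of per-gene insertion indices between replicates."""
    a = {s.gene_id: s.insertion_index for s in stats_a}
    b = {s.gene_id: s.insertion_index for s in stats_b}
    if set(a) != set(b):
        raise ValueError("replicates cover different gene universes")
    genes = sorted(a)
    if len(genes) < 3:
        raise ValueError("need at least 3 genes for a meaningful correlation")
    x = np.array([a[g] for g in genes])
    y = np.array([b[g] for g in genes])
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined: zero variance in insertion indices")
    r = float(sps.pearsonr(x, y).statistic)
    return CorrelationReport(n_genes=len(genes), pearson_r=r, r_squared=r * r)


def position_track(profile: InsertionProfile) -> pd.DataFrame:
    """BED-like 4-column per-position count track (plotting convenience)."""
    pos, strand, cnt = profile.arrays()
    return pd.DataFrame(
        {
            "replicon": profile.replicon_id,
            "start": pos - 1,  # BED half-open
            "end": pos,
            "read_count": cnt,
        }
    )
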