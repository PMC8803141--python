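"""Genome and gene-annotation containers with FASTA/GFF3 round-trip.

Coordinates are 1-based inclusive throughout, matching GFF3. Replicons are
treated as linear: simulated genes and insertions never span the origin, so
no wraparound arithmetic is needed downstream.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from functools import cached_property

import gffutils
import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

#: Length (bp) of the E. coli K-12 MG1655 chromosome, accession CP009273.1.
#: Used when expressing genome-wide insertion density for a library mapped to
#: that reference without bundling the sequence itself.
MG1655_CHROMOSOME_LENGTH_BP = 4_641_652

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class GeneModel:
    """A protein-coding (or any) gene interval on a replicon."""

    gene_id: str
    start: int  # 1-based inclusive
    end: int    # 1-based inclusive
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise ValueError(
                f"gene {self.gene_id}: invalid interval [{self.start}, {self.end}]"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be '+' or '-'")

    @property
    def length_bp(self) -> int:
        return self.end - self.start + 1

    def contains(self, position: int) -> bool:
        return self.start <= position <= self.end


@dataclass
class AnnotatedGenome:
    """A single replicon sequence plus its gene models.

    Gene intervals must lie within the sequence and carry unique identifiers.
    Overlapping genes are tolerated by the container (downstream per-gene
    summaries credit a site to every covering gene); the simulator never
    produces them.
    """

    replicon_id: str
    sequence: str
    genes: list[GeneModel] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        if set(self.sequence) - set("ACGTN"):
            raise ValueError("sequence may contain only A/C/G/T/N")
        seen: set[str] = set()
        for g in self.genes:
            if g.end > len(self.sequence):
                raise ValueError(f"gene {g.gene_id} extends past replicon end")
            if g.gene_id in seen:
                raise ValueError(f"duplicate gene_id {g.gene_id!r}")
            seen.add(g.gene_id)
        self.genes = sorted(self.genes, key=lambda g: (g.start, g.end))

    def __len__(self) -> int:
        return len(self.sequence)

    @cached_property
    def gene_ids(self) -> list[str]:
        return [g.gene_id for g in self.genes]

    @cached_property
    def _starts(self) -> np.ndarray:
        return np.array([g.start for g in self.genes], dtype=np.int64)

    @cached_property
    def _ends(self) -> np.ndarray:
        return np.array([g.end for g in self.genes], dtype=np.int64)

    def gene_index_of(self, positions: np.ndarray) -> np.ndarray:
        """Index into ``self.genes`` of the gene covering each position, or -1.

        Assumes non-overlapping genes (the simulator's guarantee); with
        overlaps only the left-most covering gene is reported here.
        """
        positions = np.asarray(positions, dtype=np.int64)
        if not self.genes:
            return np.full(positions.shape, -1, dtype=np.int64)
        idx = np.searchsorted(self._starts, positions, side="right") - 1
        idx = np.clip(idx, 0, len(self.genes) - 1)
        covered = (self._starts[idx] <= positions) & (positions <= self._ends[idx])
        return np.where(covered, idx, -1)

    # ------------------------------------------------------------------ I/O

    def write_fasta(self, path: str | os.PathLike) -> None:
        record = SeqRecord(Seq(self.sequence), id=self.replicon_id, description="")
        with open(path, "w") as fh:
            SeqIO.write([record], fh, "fasta")

    def write_gff3(self, path: str | os.PathLike) -> None:
        with open(path, "w") as fh:
            fh.write("##gff-version 3\n")
            fh.write(f"##sequence-region {self.replicon_id} 1 {len(self)}\n")
            for g in self.genes:
                fh.write(
                    "\t".join(
                        (
                            self.replicon_id,
                            "tnfit",
                            "gene",
                            str(g.start),
                            str(g.end),
                            ".",
                            g.strand,
                            ".",
                            f"ID={g.gene_id}",
                        )
                    )
                    + "\n"
                )

    @classmethod
    def read(cls, fasta_path: str | os.PathLike, gff3_path: str | os.PathLike) -> "AnnotatedGenome":
        records = list(SeqIO.parse(str(fasta_path), "fasta"))
        if len(records) != 1:
            raise ValueError("expected exactly one replicon in the FASTA file")
        rec = records[0]
        db = gffutils.create_db(
            str(gff3_path),
            ":memory:",
            merge_strategy="create_unique",
            keep_order=True,
        )
        genes = [
            GeneModel(
                gene_id=feat.id,
                start=feat.start,
                end=feat.end,
                strand=feat.strand if feat.strand in ("+", "-") else "+",
            )
            for feat in db.features_of_type("gene")
        ]
        return cls(replicon_id=rec.id, sequence=str(rec.seq), genes=genes)
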