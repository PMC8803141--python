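"""Junction-read processing: demultiplex, tag trim, map, tally.

Raw TraDIS reads have the structure ``inline barcode + transposon tag +
genomic junction``. Processing identifies the sample from the barcode
prefix, verifies and strips the transposon tag (tolerating a few
substitutions), drops short junctions, places each junction on the genome,
and tallies unique insertion sites per sample.

Mapping is pigeonhole seed-and-verify: the junction is split into
``max_mismatch + 1`` seeds, any exact seed hit proposes a placement, and a
placement is accepted if the full junction matches with at most
``max_mismatch`` substitutions (no gaps). With more than one best placement
the read is ambiguous and discarded rather than randomly assigned, which
avoids fabricating insertion sites inside repeats. A SAM file from an
external mapper can be ingested instead (RNAME/POS/FLAG only).
"""

from __future__ import annotations

import gzip
import json
import os
from dataclasses import dataclass, field, asdict
from typing import Iterable, Iterator

from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .genome import AnnotatedGenome, reverse_complement
from .profiles import InsertionProfile

DEFAULT_MIN_JUNCTION_LEN = 20
DEFAULT_SEED_K = 13

# trim_tag / mapping status codes
TAG_MISMATCH = "tag_mismatch"
SHORT_READ = "short_read"
AMBIGUOUS = "ambiguous"
UNMAPPED = "unmapped"


class BarcodeTableError(ValueError):
    """Barcode table is not prefix-free (one barcode prefixes another)."""


@dataclass(frozen=True)
class MappedSite:
    replicon_id: str
    position: int  # 1-based first genomic base of the junction
    strand: str


@dataclass
class ProcessingReport:
    """Read-funnel counters; each stage passes a subset of the previous."""

    total_reads: int = 0
    barcode_matched: int = 0
    tag_matched: int = 0
    passed_length_filter: int = 0
    mapped_unique: int = 0
    mapped_ambiguous: int = 0
    unmapped: int = 0

    def validate(self) -> None:
        funnel = (
            self.total_reads,
            self.barcode_matched,
            self.tag_matched,
            self.passed_length_filter,
        )
        if any(a < b for a, b in zip(funnel, funnel[1:])):
            raise AssertionError(f"funnel counters increased: {funnel}")
        if self.mapped_unique + self.mapped_ambiguous + self.unmapped != self.passed_length_filter:
            raise AssertionError("mapping counters do not partition the filtered reads")

    def write_json(self, path: str | os.PathLike) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)
            fh.write("\n")


def validate_barcodes(barcode_table: dict[str, str]) -> None:
    codes = list(barcode_table.values())
    if len(set(codes)) != len(codes):
        raise BarcodeTableError("duplicate barcodes in table")
    for a in codes:
        for b in codes:
            if a != b and b.startswith(a):
                raise BarcodeTableError(f"barcode {a!r} is a prefix of {b!r}")


def demultiplex(sequence: str, barcode_table: dict[str, str]) -> str | None:
    """Sample id whose barcode exactly matches the read prefix, else None.

    The table must be prefix-free (checked by :func:`validate_barcodes` at
    load time), so at most one barcode can match.
    """
    for sample_id, code in barcode_table.items():
        if sequence.startswith(code):
            return sample_id
    return None


def trim_tag(
    seq_after_barcode: str,
    tag_seq: str,
    max_mismatch: int = 0,
    min_junction_len: int = DEFAULT_MIN_JUNCTION_LEN,
) -> tuple[str | None, str | None]:
    """Strip the transposon tag; returns (junction, None) or (None, code).

    The leading ``len(tag_seq)`` bases must match the tag with at most
    ``max_mismatch`` substitutions. A matching read whose remainder is
    shorter than ``min_junction_len`` is rejected with the distinct
    short-read code.
    """
    if not tag_seq:
        raise ValueError("tag_seq must be nonempty")
    head = seq_after_barcode[: len(tag_seq)]
    if len(head) < len(tag_seq):
        return None, TAG_MISMATCH
    mismatches = sum(a != b for a, b in zip(head, tag_seq))
    if mismatches > max_mismatch:
        return None, TAG_MISMATCH
    junction = seq_after_barcode[len(tag_seq) :]
    if len(junction) < min_junction_len:
        return None, SHORT_READ
    return junction, None


class KmerIndex:
    """Exact k-mer index of both genome strands for seed-and-verify mapping.

    Coordinates returned follow the first-genomic-base convention: the
    reported position is the genomic coordinate of the first junction base
    on the matched strand (for a minus-strand junction this is the highest
    forward coordinate of the matched interval).
    """

    def __init__(self, genome: AnnotatedGenome, seed_k: int = DEFAULT_SEED_K):
        if seed_k < 8:
            raise ValueError("seed_k below 8 would flood the index with spurious hits")
        self.genome = genome
        self.seed_k = seed_k
        self.forward = genome.sequence
        self.reverse = reverse_complement(genome.sequence)
        self._index: dict[str, list[tuple[str, int]]] = {}
        for strand, seq in (("+", self.forward), ("-", self.reverse)):
            for i in range(len(seq) - seed_k + 1):
                self._index.setdefault(seq[i : i + seed_k], []).append((strand, i))

    def _verify(self, junction: str, strand: str, start0: int) -> int | None:
        """Mismatch count of the full junction at a 0-based strand offset."""
        seq = self.forward if strand == "+" else self.reverse
        if start0 < 0 or start0 + len(junction) > len(seq):
            return None
        window = seq[start0 : start0 + len(junction)]
        return sum(a != b for a, b in zip(junction, window))

    def map_junction(
        self, junction: str, max_mismatch: int = 0
    ) -> MappedSite | str:
        """Place one junction; returns a MappedSite, AMBIGUOUS or UNMAPPED."""
        k = self.seed_k
        if len(junction) < k:
            return UNMAPPED
        # pigeonhole: with <= max_mismatch errors, at least one of
        # max_mismatch+1 disjoint seeds is error-free (when they fit)
        n_seeds = max_mismatch + 1
        offsets = [i * k for i in range(n_seeds) if i * k + k <= len(junction)] or [0]
        candidates: set[tuple[str, int]] = set()
        for off in offsets:
            for strand, hit in self._index.get(junction[off : off + k], ()):
                candidates.add((strand, hit - off))
        best: list[tuple[str, int]] = []
        best_mm = max_mismatch + 1
        for strand, start0 in sorted(candidates):
            mm = self._verify(junction, strand, start0)
            if mm is None or mm > max_mismatch:
                continue
            if mm < best_mm:
                best, best_mm = [(strand, start0)], mm
            elif mm == best_mm:
                best.append((strand, start0))
        if not best:
            return UNMAPPED
        if len(best) > 1:
            return AMBIGUOUS
        strand, start0 = best[0]
        L = len(self.forward)
        position = start0 + 1 if strand == "+" else L - start0
        return MappedSite(self.genome.replicon_id, position, strand)


def tally_profile(sites: Iterable[MappedSite], sample_id: str) -> InsertionProfile:
    """Aggregate mapped sites into a per-sample insertion profile."""
    counts: dict[tuple[int, str], int] = {}
    replicon = None
    for site in sites:
        if replicon is None:
            replicon = site.replicon_id
        elif site.replicon_id != replicon:
            raise ValueError("tally_profile expects sites from a single replicon")
        key = (site.position, site.strand)
        counts[key] = counts.get(key, 0) + 1
    return InsertionProfile(sample_id, replicon or "", counts)


def _open_maybe_gz(path: str | os.PathLike):
    if str(path).endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path)


def iter_fastq(path: str | os.PathLike) -> Iterator[tuple[str, str, str]]:
    with _open_maybe_gz(path) as fh:
        yield from FastqGeneralIterator(fh)


def process_fastq(
    fastq_paths: Iterable[str | os.PathLike],
    genome: AnnotatedGenome,
    barcode_table: dict[str, str],
    tag_seq: str,
    max_mismatch: int = 2,
    min_junction_len: int = DEFAULT_MIN_JUNCTION_LEN,
    seed_k: int = DEFAULT_SEED_K,
    collapse_strands: bool = False,
    index: KmerIndex | None = None,
) -> tuple[dict[str, InsertionProfile], ProcessingReport]:
    """Full FASTQ -> per-sample insertion-profile funnel.

    Returns one profile per sample in ``barcode_table`` (possibly empty) and
    the funnel report. ``max_mismatch`` bounds substitutions both in the tag
    and in the mapped junction.
    """
    validate_barcodes(barcode_table)
    if index is None:
        index = KmerIndex(genome, seed_k=seed_k)
    report = ProcessingReport()
    per_sample: dict[str, dict[tuple[int, str], int]] = {s: {} for s in barcode_table}
    for path in fastq_paths:
        for _, seq, _ in iter_fastq(path):
            report.total_reads += 1
            sample = demultiplex(seq, barcode_table)
            if sample is None:
                continue
            report.barcode_matched += 1
            junction, code = trim_tag(
                seq[len(barcode_table[sample]) :],
                tag_seq,
                max_mismatch=max_mismatch,
                min_junction_len=min_junction_len,
            )
            if junction is None:
                if code == SHORT_READ:
                    report.tag_matched += 1
                continue
            report.tag_matched += 1
            report.passed_length_filter += 1
            hit = index.map_junction(junction, max_mismatch=max_mismatch)
            if hit == AMBIGUOUS:
                report.mapped_ambiguous += 1
            elif hit == UNMAPPED:
                report.unmapped += 1
            else:
                report.mapped_unique += 1
                key = (hit.position, hit.strand)
                counts = per_sample[sample]
                counts[key] = counts.get(key, 0) + 1
    profiles = {
        s: InsertionProfile(s, genome.replicon_id, counts)
        for s, counts in per_sample.items()
    }
    if collapse_strands:
        profiles = {s: p.collapse_strands() for s, p in profiles.items()}
    report.validate()
    return profiles, report


def profile_from_sam(
    sam_path: str | os.PathLike, sample_id: str, replicon_id: str | None = None
) -> InsertionProfile:
    """Ingest an externally produced SAM file (RNAME/POS/FLAG only).

    Primary mapped alignments are tallied at POS with the strand taken from
    FLAG bit 0x10; an alternative to the built-in seed-and-verify mapper.
    """
    counts: dict[tuple[int, str], int] = {}
    rname = replicon_id
    with open(sam_path) as fh:
        for line in fh:
            if line.startswith("@"):
                continue
            fields = line.rstrip("\n").split("\t")
            flag = int(fields[1])
            if flag & 0x4 or flag & 0x100 or flag & 0x800:  # unmapped/secondary/supp
                continue
            if rname is None:
                rname = fields[2]
            elif fields[2] != rname:
                continue
            strand = "-" if flag & 0x10 else "+"
            key = (int(fields[3]), strand)
            counts[key] = counts.get(key, 0) + 1
    return InsertionProfile(sample_id, rname or "", counts)
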