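"""Synthetic transposon-insertion libraries with known ground truth.

The generator emulates a dense mini-Tn5 library in a bacterial chromosome:
insertion sites scattered ~every 10 bp genome-wide, essential genes devoid
of insertions, overdispersed per-site read counts, and treated samples in
which designated genes are depleted or enriched with chosen log2 effects.
Every downstream stage of the package is testable against the ground truth
these functions record.

All randomness flows from a single integer seed through
``numpy.random.SeedSequence`` spawning, so each stage is independently
reproducible and two calls with the same arguments are byte-identical.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome import AnnotatedGenome, GeneModel, reverse_complement
from .profiles import InsertionProfile

#: Genome-wide insertion density of the library being emulated: one unique
#: site per 10.3 bp of chromosome.
DEFAULT_INSERTIONS_PER_BP = 1.0 / 10.3

#: Mean reads per unique site (the emulated library has ~4.42e6 reads over
#: ~4.51e5 sites, i.e. ~9.8 reads/site; rounded to 10).
DEFAULT_MEAN_READS_PER_SITE = 10.0

#: NB dispersion alpha (variance = mu + alpha*mu^2) for per-site read counts;
#: 0.3 gives realistic overdispersion for PCR-amplified junction libraries.
DEFAULT_NB_DISPERSION = 0.3

#: EZ-Tn5 mosaic-end sequence: the transposon-side tag expected at the start
#: of every junction read, after the inline barcode.
DEFAULT_TAG = "CTGTCTCTTATACACATCT"


class SizingError(ValueError):
    """Requested genes cannot be packed into the requested genome length."""


@dataclass(frozen=True)
class GeneEffect:
    essential: bool = False
    fitness_log2: float = 0.0


@dataclass
class EffectMap:
    """Ground-truth per-gene effects: essentiality and selection strength.

    ``fitness_log2`` is the per-unit-treatment log2 change in mutant
    abundance (0 = neutral, negative = insertions lose fitness under the
    stress, ``-inf`` = hard kill). Essential genes carry no insertions, so
    their fitness value is never applied.
    """

    effects: dict[str, GeneEffect] = field(default_factory=dict)

    def __getitem__(self, gene_id: str) -> GeneEffect:
        return self.effects[gene_id]

    def validate_against(self, genome: AnnotatedGenome) -> None:
        missing = set(genome.gene_ids) - set(self.effects)
        extra = set(self.effects) - set(genome.gene_ids)
        if missing or extra:
            raise ValueError(
                f"effect map does not cover the genome exactly: "
                f"missing={sorted(missing)[:5]} extra={sorted(extra)[:5]}"
            )

    @classmethod
    def neutral(cls, genome: AnnotatedGenome) -> "EffectMap":
        return cls({g: GeneEffect() for g in genome.gene_ids})

    def scaled(self, factor: float) -> "EffectMap":
        """Effect map with every fitness_log2 multiplied by ``factor``.

        Used to model a longer/stronger treatment as a scaling of the same
        underlying per-gene effects.
        """
        return EffectMap(
            {
                g: GeneEffect(e.essential, e.fitness_log2 * factor)
                for g, e in self.effects.items()
            }
        )

    def true_class(self, gene_id: str, lfc_threshold: float = 1.0) -> str:
        e = self.effects[gene_id]
        if e.essential:
            return "essential"
        if e.fitness_log2 < -lfc_threshold:
            return "loss"
        if e.fitness_log2 > lfc_threshold:
            return "gain"
        return "neutral"

    def write_tsv(self, path: str | os.PathLike) -> None:
        df = pd.DataFrame(
            {
                "gene_id": sorted(self.effects),
                "essential": [int(self.effects[g].essential) for g in sorted(self.effects)],
                "fitness_log2": [self.effects[g].fitness_log2 for g in sorted(self.effects)],
            }
        )
        df.to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path: str | os.PathLike) -> "EffectMap":
        df = pd.read_csv(path, sep="\t")
        return cls(
            {
                str(r.gene_id): GeneEffect(bool(r.essential), float(r.fitness_log2))
                for r in df.itertuples()
            }
        )


def _child_rng(seed: int, *path: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=tuple(path)))


# --------------------------------------------------------------------------
# genome


def generate_genome(
    length_bp: int,
    n_genes: int,
    gc_fraction: float = 0.5,
    seed: int = 0,
    mean_gene_length: int = 900,
    min_gene_length: int = 150,
    replicon_id: str = "sim_chr",
) -> AnnotatedGenome:
    """Random linear genome with ``n_genes`` non-overlapping genes.

    Gene lengths are gamma-distributed around ``mean_gene_length`` (shape 4,
    clipped below at ``min_gene_length``), intergenic gaps are at least 1 bp,
    and strands are assigned uniformly. Deterministic for a fixed seed.
    """
    if not 0.0 < gc_fraction < 1.0:
        raise ValueError("gc_fraction must be in (0, 1)")
    if n_genes > 0 and length_bp < n_genes * 100:
        raise SizingError(f"{n_genes} genes cannot fit in {length_bp} bp (need >= 100 bp/gene)")
    rng = _child_rng(seed, 0)

    p = np.array(
        [(1 - gc_fraction) / 2, gc_fraction / 2, gc_fraction / 2, (1 - gc_fraction) / 2]
    )
    bases = rng.choice(np.frombuffer(b"ACGT", dtype="S1"), size=length_bp, p=p)
    sequence = bases.tobytes().decode("ascii")

    genes: list[GeneModel] = []
    if n_genes > 0:
        shape = 4.0
        lengths = rng.gamma(shape, mean_gene_length / shape, size=n_genes)
        lengths = np.maximum(lengths.astype(np.int64), min_gene_length)
        # shrink proportionally if the draw cannot be packed with >=1 bp gaps
        budget = length_bp - (n_genes + 1)
        if lengths.sum() > budget:
            lengths = np.maximum((lengths * budget / lengths.sum()).astype(np.int64), 100)
            if lengths.sum() > budget:
                raise SizingError("genes cannot be packed with the required gaps")
        slack = int(length_bp - lengths.sum() - (n_genes + 1))
        extra = rng.multinomial(slack, np.full(n_genes + 1, 1.0 / (n_genes + 1)))
        strands = rng.choice(np.array(["+", "-"]), size=n_genes)
        width = len(str(n_genes))
        cursor = 1
        for i in range(n_genes):
            cursor += 1 + int(extra[i])  # gap of >=1 bp before each gene
            start = cursor
            end = start + int(lengths[i]) - 1
            genes.append(
                GeneModel(f"g{i + 1:0{width}d}", start, end, str(strands[i]))
            )
            cursor = end + 1
    return AnnotatedGenome(replicon_id=replicon_id, sequence=sequence, genes=genes)


def random_effects(
    genome: AnnotatedGenome,
    n_essential: int = 0,
    n_loss: int = 0,
    n_gain: int = 0,
    loss_log2: float = -3.0,
    gain_log2: float = 2.0,
    seed: int = 0,
) -> EffectMap:
    """Assign essential / loss / gain classes to randomly chosen genes."""
    ids = list(genome.gene_ids)
    if n_essential + n_loss + n_gain > len(ids):
        raise ValueError("more effect genes requested than genes in the genome")
    rng = _child_rng(seed, 1)
    chosen = rng.permutation(len(ids))
    effects = {g: GeneEffect() for g in ids}
    k = 0
    for _ in range(n_essential):
        effects[ids[chosen[k]]] = GeneEffect(essential=True)
        k += 1
    for _ in range(n_loss):
        effects[ids[chosen[k]]] = GeneEffect(fitness_log2=loss_log2)
        k += 1
    for _ in range(n_gain):
        effects[ids[chosen[k]]] = GeneEffect(fitness_log2=gain_log2)
        k += 1
    return EffectMap(effects)


# --------------------------------------------------------------------------
# library


def _essential_mask(genome: AnnotatedGenome, effects: EffectMap) -> np.ndarray:
    mask = np.zeros(len(genome) + 1, dtype=bool)  # 1-based indexing
    for g in genome.genes:
        if effects[g.gene_id].essential:
            mask[g.start : g.end + 1] = True
    return mask


def simulate_library(
    genome: AnnotatedGenome,
    effects: EffectMap,
    insertions_per_bp: float = DEFAULT_INSERTIONS_PER_BP,
    mean_reads_per_site: float = DEFAULT_MEAN_READS_PER_SITE,
    nb_dispersion: float = DEFAULT_NB_DISPERSION,
    seed: int = 0,
    edge_margin: int = 0,
    sample_id: str = "library",
) -> InsertionProfile:
    """Draw a saturating insertion library over the genome.

    Each base outside essential genes (and outside ``edge_margin`` bp of the
    replicon ends) independently receives an insertion with probability
    ``insertions_per_bp``; the strand is uniform. Per-site read counts are
    zero-truncated negative binomial with mean ``mean_reads_per_site`` and
    dispersion ``nb_dispersion`` (variance mu + alpha*mu^2): a site with no
    reads would never be observed, so counts are conditioned positive and
    the unique-site count stays Binomial(L_accessible, insertions_per_bp).
    """
    if insertions_per_bp < 0:
        raise ValueError("insertions_per_bp must be >= 0")
    if mean_reads_per_site <= 0 or nb_dispersion < 0:
        raise ValueError("mean_reads_per_site must be > 0 and nb_dispersion >= 0")
    effects.validate_against(genome)
    rng = _child_rng(seed, 2)
    L = len(genome)
    if insertions_per_bp == 0 or L == 0:
        return InsertionProfile(sample_id, genome.replicon_id, {})

    accessible = ~_essential_mask(genome, effects)
    accessible[0] = False  # index 0 unused (1-based coordinates)
    if edge_margin > 0:
        accessible[1 : min(edge_margin, L) + 1] = False
        accessible[max(L - edge_margin + 1, 1) :] = False

    hits = rng.random(L + 1) < insertions_per_bp
    positions = np.flatnonzero(hits & accessible)
    n = positions.size
    if n == 0:
        return InsertionProfile(sample_id, genome.replicon_id, {})
    strands = np.where(rng.random(n) < 0.5, "+", "-")
    counts = _truncated_nb(rng, mean_reads_per_site, nb_dispersion, n)
    profile = {
        (int(p), str(s)): int(c) for p, s, c in zip(positions, strands, counts)
    }
    return InsertionProfile(sample_id, genome.replicon_id, profile)


def _truncated_nb(
    rng: np.random.Generator, mean: float, alpha: float, n: int
) -> np.ndarray:
    """Zero-truncated NB(mean, alpha) draws (Poisson when alpha == 0)."""

    def draw(k: int) -> np.ndarray:
        if alpha == 0:
            return rng.poisson(mean, size=k)
        size = 1.0 / alpha
        return rng.negative_binomial(size, size / (size + mean), size=k)

    out = draw(n)
    zero = np.flatnonzero(out == 0)
    while zero.size:
        out[zero] = draw(zero.size)
        zero = zero[out[zero] == 0]
    return out


def apply_selection(
    control: InsertionProfile,
    genome: AnnotatedGenome,
    effects: EffectMap,
    seed: int = 0,
    total_reads: int | None = None,
    sample_id: str | None = None,
) -> InsertionProfile:
    """Resample reads under per-gene selection.

    The treated profile is a multinomial resampling of ``total_reads`` reads
    (default: the control total, preserved exactly) with per-site weight
    proportional to ``count * 2**fitness_log2`` of the covering gene
    (weight factor 1 for intergenic sites, 0 for ``-inf`` hard kills).
    The treated site set is a subset of the control's. With an all-neutral
    effect map this is a pure sequencing resample of the same library —
    which is how replicate samples of one physical library are modeled.
    """
    if control.n_sites == 0:
        raise ValueError("control profile is empty")
    effects.validate_against(genome)
    rng = _child_rng(seed, 3)
    pos, strand, cnt = control.arrays()
    gidx = genome.gene_index_of(pos)
    log2f = np.zeros(pos.size)
    for i, g in enumerate(genome.genes):
        sel = gidx == i
        if sel.any():
            log2f[sel] = effects[g.gene_id].fitness_log2
    weights = cnt.astype(float) * np.exp2(log2f)
    total = control.total_reads if total_reads is None else int(total_reads)
    wsum = weights.sum()
    if wsum <= 0:
        raise ValueError("all site weights are zero; nothing to resample")
    new_counts = rng.multinomial(total, weights / wsum)
    name = sample_id if sample_id is not None else f"{control.sample_id}_sel"
    profile = {
        (int(p), str(s)): int(c)
        for p, s, c in zip(pos, strand, new_counts)
        if c > 0
    }
    return InsertionProfile(name, control.replicon_id, profile)


# --------------------------------------------------------------------------
# reads


def emit_reads(
    profile: InsertionProfile,
    genome: AnnotatedGenome,
    tag_seq: str = DEFAULT_TAG,
    barcode: str = "ACGTAC",
    read_length: int = 75,
    error_rate: float = 0.0,
    seed: int = 0,
    quality_char: str = "?",  # Phred Q30
):
    """Yield (read_id, sequence, quality) junction reads for every counted read.

    Each read is ``barcode + tag_seq + genomic junction`` starting at the
    insertion position on the recorded strand; reads too close to the
    replicon end are truncated (linear convention, never wrapped).
    Substitution errors are applied per base at ``error_rate`` across the
    whole read; qualities are constant. Read ids encode the true origin as
    ``sample|position|strand|serial`` for ground-truth bookkeeping.
    """
    if read_length <= len(barcode) + len(tag_seq) + 10:
        raise ValueError("read_length must exceed barcode+tag length by more than 10")
    rng = _child_rng(seed, 4)
    L = len(genome)
    prefix = barcode + tag_seq
    max_junction = read_length - len(prefix)
    serial = 0
    for (pos, strand) in profile.sorted_sites():
        count = profile.counts[(pos, strand)]
        if strand == "+":
            junction = genome.sequence[pos - 1 : min(L, pos - 1 + max_junction)]
        else:
            lo = max(0, pos - max_junction)
            junction = reverse_complement(genome.sequence[lo:pos])
        base_seq = prefix + junction
        for _ in range(count):
            seq = base_seq
            if error_rate > 0:
                seq = _mutate(rng, seq, error_rate)
            read_id = f"{profile.sample_id}|{pos}|{strand}|{serial}"
            serial += 1
            yield read_id, seq, quality_char * len(seq)


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    hit = np.flatnonzero(rng.random(arr.size) < rate)
    if hit.size == 0:
        return seq
    alphabet = np.frombuffer(b"ACGT", dtype="S1")
    for i in hit:
        choices = alphabet[alphabet != arr[i]]
        arr[i] = choices[rng.integers(len(choices))]
    return arr.tobytes().decode()


def write_fastq(reads, path: str | os.PathLike) -> int:
    """Write an iterable of (id, seq, qual) as a 4-line-record FASTQ file."""
    n = 0
    with open(path, "w") as fh:
        for read_id, seq, qual in reads:
            fh.write(f"@{read_id}\n{seq}\n+\n{qual}\n")
            n += 1
    return n


def expected_unique_sites(accessible_bp: int, insertions_per_bp: float) -> tuple[float, float]:
    """Binomial mean and SD of the unique-site count of a simulated library."""
    mean = accessible_bp * insertions_per_bp
    sd = math.sqrt(accessible_bp * insertions_per_bp * (1 - insertions_per_bp))
    return mean, sd
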