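"""Calibration experiments run entirely on simulated ground truth.

These functions wire the simulator to the analysis stack at realistic
problem sizes and measure how well the statistics recover known truth:
the type-I error of the gated exact test on a null library, sensitivity
and false discovery on engineered loss/gain effects, essentiality-call
recovery, and replicate agreement. They operate on insertion profiles
directly (no read emission), which is exact for every statistic involved
because error-free read processing reproduces profiles identically.

Each experiment takes a single integer seed and is deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import fitness as fit
from .essentiality import fit_essentiality_mixture
from .genome import AnnotatedGenome
from .insertion import replicate_correlation, summarize_genes
from .simulate import (
    EffectMap,
    apply_selection,
    generate_genome,
    random_effects,
    simulate_library,
)

#: Default scale of the calibration experiments: a 4.2 Mb genome carrying
#: 4,000 genes sampled at one insertion per 10.3 bp with ~10 reads/site,
#: i.e. several hundred reads per gene and two replicates per condition.
DEFAULT_N_GENES = 4000
DEFAULT_GENOME_BP = 4_200_000


def _experiment_genome(seed: int, n_genes: int = DEFAULT_N_GENES,
                       length_bp: int = DEFAULT_GENOME_BP) -> AnnotatedGenome:
    return generate_genome(length_bp, n_genes, gc_fraction=0.5, seed=seed)


def _gene_read_counts(profile, genome) -> pd.Series:
    stats = summarize_genes(profile, genome)
    return pd.Series({s.gene_id: s.read_count for s in stats})


def _counts_matrix(genome, master, effect_map, seed: int, replicates: int = 2):
    """Simulate 2+2 (control, treated) samples as resamplings of one master."""
    neutral = EffectMap.neutral(genome)
    cols = {}
    design = {}
    for r in range(replicates):
        name = f"c{r + 1}"
        prof = apply_selection(master, genome, neutral, seed=seed * 10 + r)
        cols[name] = _gene_read_counts(prof, genome)
        design[name] = fit.CONTROL
    for r in range(replicates):
        name = f"t{r + 1}"
        prof = apply_selection(master, genome, effect_map, seed=seed * 10 + 100 + r)
        cols[name] = _gene_read_counts(prof, genome)
        design[name] = fit.TREATED
    return pd.DataFrame(cols), design


@dataclass(frozen=True)
class NullResult:
    n_gene_tests: int
    n_gated: int

    @property
    def gated_fraction(self) -> float:
        return self.n_gated / self.n_gene_tests


def null_false_positive_rate(
    seed: int,
    n_seeds: int = 10,
    n_genes: int = DEFAULT_N_GENES,
    genome_bp: int = DEFAULT_GENOME_BP,
) -> NullResult:
    """Fraction of genes gated loss/gain when no gene has any true effect.

    One master library; per repetition, 2 control + 2 'treated' samples are
    drawn as independent resamplings of it, so every gated gene is a false
    positive.
    """
    genome = _experiment_genome(seed, n_genes, genome_bp)
    effects = random_effects(genome, seed=seed)  # all neutral
    master = simulate_library(genome, effects, seed=seed)
    total = gated = 0
    for rep in range(n_seeds):
        counts, design = _counts_matrix(genome, master, EffectMap.neutral(genome),
                                        seed=seed + 1000 * (rep + 1))
        results = fit.fitness_table(counts, design)
        total += len(results)
        gated += int((results["sig_class"] != "ns").sum())
    return NullResult(n_gene_tests=total, n_gated=gated)


@dataclass(frozen=True)
class RecoveryResult:
    n_true_effect: int
    n_correct: int
    n_gated: int
    n_false_discoveries: int
    log2fc_rmse: float  # over true-effect genes with >= min_reads control reads

    @property
    def sensitivity(self) -> float:
        return self.n_correct / self.n_true_effect

    @property
    def false_discovery_rate(self) -> float:
        return self.n_false_discoveries / self.n_gated if self.n_gated else 0.0


def effect_recovery(
    seed: int,
    n_genes: int = DEFAULT_N_GENES,
    genome_bp: int = DEFAULT_GENOME_BP,
    n_loss: int = 30,
    n_gain: int = 10,
    loss_log2: float = -3.0,
    gain_log2: float = 2.0,
    min_reads: int = 200,
) -> RecoveryResult:
    """Recovery of engineered depletion/enrichment effects.

    Measures the fraction of true-effect genes gated in the correct class,
    the empirical false-discovery rate among gated genes, and the log2FC
    RMSE over true-effect genes with at least ``min_reads`` mean control
    reads.
    """
    genome = _experiment_genome(seed, n_genes, genome_bp)
    effects = random_effects(genome, n_loss=n_loss, n_gain=n_gain,
                             loss_log2=loss_log2, gain_log2=gain_log2, seed=seed)
    master = simulate_library(genome, effects, seed=seed)
    counts, design = _counts_matrix(genome, master, effects, seed=seed + 17)
    results = fit.fitness_table(counts, design)

    truth = {g: effects.true_class(g) for g in genome.gene_ids}
    correct = 0
    false_disc = 0
    gated = 0
    sq_err = []
    ctrl_cols = [s for s, g in design.items() if g == fit.CONTROL]
    mean_ctrl = counts[ctrl_cols].mean(axis=1)
    for g, row in results.iterrows():
        t = truth[g]
        s = row["sig_class"]
        if s != "ns":
            gated += 1
            if t == "neutral":
                false_disc += 1
        if t in ("loss", "gain"):
            if s == t:
                correct += 1
            if mean_ctrl[g] >= min_reads:
                f_true = effects[g].fitness_log2
                sq_err.append((row["log2fc"] - f_true) ** 2)
    rmse = float(np.sqrt(np.mean(sq_err))) if sq_err else float("nan")
    return RecoveryResult(
        n_true_effect=n_loss + n_gain,
        n_correct=correct,
        n_gated=gated,
        n_false_discoveries=false_disc,
        log2fc_rmse=rmse,
    )


@dataclass(frozen=True)
class EssentialityRecovery:
    n_essential: int
    n_nonessential: int
    n_true_positive: int
    n_false_positive: int

    @property
    def sensitivity(self) -> float:
        return self.n_true_positive / self.n_essential

    @property
    def false_call_rate(self) -> float:
        return self.n_false_positive / self.n_nonessential


def essentiality_recovery(
    seed: int,
    n_genes: int = DEFAULT_N_GENES,
    genome_bp: int = DEFAULT_GENOME_BP,
    n_essential: int = 400,
) -> EssentialityRecovery:
    """Recovery of insertion-free (essential) genes by the mixture model."""
    genome = _experiment_genome(seed, n_genes, genome_bp)
    effects = random_effects(genome, n_essential=n_essential, seed=seed)
    master = simulate_library(genome, effects, seed=seed)
    stats = summarize_genes(master, genome)
    indices = np.array([s.insertion_index for s in stats])
    max_len = max(g.length_bp for g in genome.genes)
    model = fit_essentiality_mixture(indices, seed=seed, floor=1 / (2 * max_len))
    llr = model.log2_likelihood_ratio(indices)
    called = llr >= 2.0
    truth = np.array([effects[s.gene_id].essential for s in stats])
    return EssentialityRecovery(
        n_essential=int(truth.sum()),
        n_nonessential=int((~truth).sum()),
        n_true_positive=int((called & truth).sum()),
        n_false_positive=int((called & ~truth).sum()),
    )


def replicate_agreement(
    seed: int,
    length_bp: int = 50_000,
    n_genes: int = 40,
    n_essential: int = 4,
    n_loss: int = 4,
    n_gain: int = 2,
) -> float:
    """Insertion-index r^2 between two replicate samples of one library.

    Replicates are independent read-level resamplings of the same master
    pool (as biological replicates of one physical library are), at the
    default demo conditions.
    """
    genome = generate_genome(length_bp, n_genes, seed=seed)
    effects = random_effects(genome, n_essential=n_essential, n_loss=n_loss,
                             n_gain=n_gain, seed=seed)
    master = simulate_library(genome, effects, seed=seed)
    neutral = EffectMap.neutral(genome)
    a = apply_selection(master, genome, neutral, seed=seed + 1)
    b = apply_selection(master, genome, neutral, seed=seed + 2)
    rep = replicate_correlation(
        summarize_genes(a, genome), summarize_genes(b, genome)
    )
    return rep.r_squared
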