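"""Conditional-fitness statistics on per-gene read counts.

The analytical core of the package: treated-vs-control comparison of
per-gene transposon read counts under a negative-binomial model with a
common dispersion. For each gene, replicates are pooled per condition
after equalizing library sizes and a two-sided exact test enumerates all
splits of the pooled total between conditions, summing the probabilities
of outcomes no more probable than the observed one. Effect size is the
log2 fold change of normalized mean counts with a small prior count
guarding zeros. Multiplicity is controlled by Bonferroni over the tested
(non-essential, nonzero) genes, and a gene is called significant only when
|log2FC| strictly exceeds the fold-change threshold AND the adjusted p is
strictly below alpha — so a gene at log2FC -0.961 or adjusted p 0.005 is
not significant, while adjusted p 0.0041 with |log2FC| > 1 is.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

DEFAULT_LFC_THRESHOLD = 1.0
DEFAULT_ALPHA = 0.005
DEFAULT_PRIOR_COUNT = 0.5

CONTROL, TREATED = "control", "treated"


@dataclass(frozen=True)
class Normalization:
    """Per-sample size factors plus a common NB dispersion estimate."""

    size_factors: pd.Series  # indexed by sample id
    dispersion: float        # phi: variance = mu + phi * mu^2

    @property
    def reference_size(self) -> float:
        return float(np.exp(np.log(self.size_factors).mean()))


@dataclass(frozen=True)
class FitnessResult:
    gene_id: str
    mean_control_count: float
    mean_treated_count: float
    log2fc: float
    p_value: float
    adj_p: float
    sig_class: str  # loss | gain | ns


@dataclass(frozen=True)
class TimepointClassification:
    both: frozenset[str]
    early_only: frozenset[str]
    late_only: frozenset[str]


def normalize_and_dispersion(
    counts: pd.DataFrame,
    design: Mapping[str, str],
    method: str = "total",
) -> Normalization:
    """Size factors and a common method-of-moments dispersion.

    ``counts`` is genes x samples (non-negative integers); ``design`` maps
    each sample column to 'control' or 'treated'. Size factors are library
    sizes (total mapped reads), optionally adjusted by a trimmed mean of
    log ratios against the geometric-mean reference ("tmm"). The common
    dispersion phi is estimated by pooling, over genes and within-condition
    replicate groups, the excess of the between-replicate variance over the
    Poisson expectation, normalized by squared means:
    phi = max(0, sum_g(v_g - m_g) / sum_g m_g^2) on depth-equalized counts.
    """
    missing = set(counts.columns) - set(design)
    if missing:
        raise ValueError(f"design missing samples: {sorted(missing)}")
    bad = set(design.values()) - {CONTROL, TREATED}
    if bad:
        raise ValueError(f"design conditions must be control/treated, got {sorted(bad)}")
    if (counts.values < 0).any():
        raise ValueError("counts must be non-negative")
    lib = counts.sum(axis=0).astype(float)
    if (lib == 0).any():
        zero = list(lib.index[lib == 0])
        raise ValueError(f"samples with zero total reads: {zero}")

    size = lib.copy()
    if method == "tmm":
        ref = counts.div(lib, axis=1).mean(axis=1)
        for s in counts.columns:
            cpm = counts[s] / lib[s]
            ok = (cpm > 0) & (ref > 0)
            logr = np.log2(cpm[ok] / ref[ok])
            trimmed = sps.trim_mean(logr, 0.3) if ok.sum() >= 10 else logr.mean()
            size[s] = lib[s] * 2.0**trimmed
    elif method != "total":
        raise ValueError(f"unknown normalization method {method!r}")

    ref_size = float(np.exp(np.log(size).mean()))
    scaled = counts * (ref_size / size)
    num = 0.0
    den = 0.0
    for cond in (CONTROL, TREATED):
        cols = [s for s in counts.columns if design[s] == cond]
        if len(cols) < 2:
            continue
        sub = scaled[cols].to_numpy(dtype=float)
        m = sub.mean(axis=1)
        v = sub.var(axis=1, ddof=1)
        keep = m > 0
        num += float((v[keep] - m[keep]).sum())
        den += float((m[keep] ** 2).sum())
    phi = max(0.0, num / den) if den > 0 else 0.0
    return Normalization(size_factors=size, dispersion=phi)


def _equalized_pooled(counts: Sequence[float], sizes, ref_size: float) -> int:
    counts = np.asarray(counts, dtype=float)
    if sizes is None:
        return int(round(counts.sum()))
    sizes = np.asarray(sizes, dtype=float)
    return int(round(float((counts * ref_size / sizes).sum())))


def nb_exact_test(
    gene_control_counts: Sequence[float],
    gene_treated_counts: Sequence[float],
    control_sizes=None,
    treated_sizes=None,
    phi: float = 0.0,
) -> float:
    """Two-sided exact NB test of a treated/control difference for one gene.

    Replicate counts are adjusted to a common library size (geometric mean
    of the size factors) and pooled per condition. Under the null the two
    pooled sums are NB with per-replicate mean ``m = T / (n_c + n_t)`` and
    sizes ``n_c/phi`` and ``n_t/phi`` (Poisson when phi == 0, in which case
    the conditional law of the split is exactly binomial). The p-value sums
    the conditional probabilities of all splits of the pooled total that
    are no more probable than the observed split.
    """
    if phi < 0:
        raise ValueError("dispersion phi must be >= 0")
    n_c, n_t = len(gene_control_counts), len(gene_treated_counts)
    if n_c == 0 or n_t == 0:
        raise ValueError("need at least one replicate per condition")
    all_sizes = None
    if control_sizes is not None or treated_sizes is not None:
        all_sizes = np.concatenate(
            [np.asarray(control_sizes, float), np.asarray(treated_sizes, float)]
        )
        ref = float(np.exp(np.log(all_sizes).mean()))
    else:
        ref = 1.0
    c = _equalized_pooled(gene_control_counts, None if all_sizes is None else control_sizes, ref)
    t = _equalized_pooled(gene_treated_counts, None if all_sizes is None else treated_sizes, ref)
    total = c + t
    if total == 0:
        return 1.0
    k = np.arange(total + 1)
    if phi == 0.0:
        logp = sps.binom.logpmf(k, total, n_c / (n_c + n_t))
    else:
        m = total / (n_c + n_t)
        size_c, size_t = n_c / phi, n_t / phi
        mean_c, mean_t = n_c * m, n_t * m
        logp = sps.nbinom.logpmf(
            k, size_c, size_c / (size_c + mean_c)
        ) + sps.nbinom.logpmf(total - k, size_t, size_t / (size_t + mean_t))
    p = np.exp(logp - logp.max())
    p_obs = p[c]
    return float(p[p <= p_obs * (1 + 1e-9)].sum() / p.sum())


def log2_fold_change(
    gene_control_counts: Sequence[float],
    gene_treated_counts: Sequence[float],
    control_sizes=None,
    treated_sizes=None,
    prior_count: float = DEFAULT_PRIOR_COUNT,
) -> float:
    """log2[(mean normalized treated + prior) / (mean normalized control + prior)]."""
    if prior_count <= 0:
        raise ValueError("prior_count must be > 0")
    ctrl = np.asarray(gene_control_counts, dtype=float)
    trt = np.asarray(gene_treated_counts, dtype=float)
    if control_sizes is not None or treated_sizes is not None:
        cs = np.asarray(control_sizes, dtype=float)
        ts = np.asarray(treated_sizes, dtype=float)
        ref = float(np.exp(np.log(np.concatenate([cs, ts])).mean()))
        ctrl = ctrl * ref / cs
        trt = trt * ref / ts
    return float(np.log2((trt.mean() + prior_count) / (ctrl.mean() + prior_count)))


def bonferroni(p: float, n_tests: int) -> float:
    """Bonferroni-adjusted p-value: min(1, p * n_tests)."""
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must be in [0, 1]")
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return min(1.0, p * n_tests)


def gate_significance(
    log2fc: float,
    adj_p: float,
    lfc_threshold: float = DEFAULT_LFC_THRESHOLD,
    alpha: float = DEFAULT_ALPHA,
) -> str:
    """Classify a gene as loss / gain / ns; both inequalities are strict."""
    if adj_p < alpha:
        if log2fc < -lfc_threshold:
            return "loss"
        if log2fc > lfc_threshold:
            return "gain"
    return "ns"


def fitness_table(
    counts: pd.DataFrame,
    design: Mapping[str, str],
    normalization: Normalization | None = None,
    lfc_threshold: float = DEFAULT_LFC_THRESHOLD,
    alpha: float = DEFAULT_ALPHA,
    prior_count: float = DEFAULT_PRIOR_COUNT,
) -> pd.DataFrame:
    """Per-gene fitness results for one treated-vs-control comparison.

    ``counts`` rows are genes (the essential genome should already have
    been excluded), columns samples. Genes with no reads in any sample are
    reported with p=1 / ns and do not count toward the Bonferroni factor;
    the number of tests is the number of genes with at least one read.
    """
    norm = normalization if normalization is not None else normalize_and_dispersion(counts, design)
    ctrl_cols = [s for s in counts.columns if design[s] == CONTROL]
    trt_cols = [s for s in counts.columns if design[s] == TREATED]
    if not ctrl_cols or not trt_cols:
        raise ValueError("need at least one control and one treated sample")
    cs = norm.size_factors[ctrl_cols].to_numpy(dtype=float)
    ts = norm.size_factors[trt_cols].to_numpy(dtype=float)
    ref = norm.reference_size

    rows = []
    tested = (counts[ctrl_cols + trt_cols].sum(axis=1) > 0).to_numpy()
    n_tests = max(1, int(tested.sum()))
    for i, gene in enumerate(counts.index):
        ctrl = counts.loc[gene, ctrl_cols].to_numpy(dtype=float)
        trt = counts.loc[gene, trt_cols].to_numpy(dtype=float)
        lfc = log2_fold_change(ctrl, trt, cs, ts, prior_count=prior_count)
        if tested[i]:
            p = nb_exact_test(ctrl, trt, cs, ts, phi=norm.dispersion)
            adj = bonferroni(p, n_tests)
        else:
            p, adj = 1.0, 1.0
        rows.append(
            {
                "gene_id": gene,
                "mean_control_count": float((ctrl * ref / cs).mean()),
                "mean_treated_count": float((trt * ref / ts).mean()),
                "log2fc": lfc,
                "p_value": p,
                "adj_p": adj,
                "sig_class": gate_significance(lfc, adj, lfc_threshold, alpha),
            }
        )
    return pd.DataFrame(rows).set_index("gene_id")


def significant_genes(results: pd.DataFrame) -> frozenset[str]:
    return frozenset(results.index[results["sig_class"] != "ns"])


def classify_timepoints(
    sig_early: frozenset[str] | set[str], sig_late: frozenset[str] | set[str]
) -> TimepointClassification:
    """Split significant gene sets of two treatment durations into
    shared / early-only / late-only subsets."""
    early, late = frozenset(sig_early), frozenset(sig_late)
    return TimepointClassification(
        both=early & late,
        early_only=early - late,
        late_only=late - early,
    )


def write_fitness_results(results: pd.DataFrame, path: str | os.PathLike) -> None:
    results.to_csv(path, sep="\t")


def write_run_summary(
    path: str | os.PathLike,
    per_timepoint: Mapping[str, pd.DataFrame],
    classification: TimepointClassification | None = None,
) -> None:
    summary: dict = {"timepoints": {}}
    for name, df in per_timepoint.items():
        vc = df["sig_class"].value_counts()
        summary["timepoints"][name] = {
            "loss": int(vc.get("loss", 0)),
            "gain": int(vc.get("gain", 0)),
            "ns": int(vc.get("ns", 0)),
        }
    if classification is not None:
        summary["sets"] = {
            "both": sorted(classification.both),
            "early_only": sorted(classification.early_only),
            "late_only": sorted(classification.late_only),
        }
    with open(path, "w") as fh:
        json.dump(summary, fh, indent=2)
        fh.write("\n")
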