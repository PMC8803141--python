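"""Essential-gene calling from the insertion-index distribution.

In a saturating transposon library the per-gene insertion indices are
bimodal: a left mode near zero (genes whose disruption is lethal, so no
insertion mutant survives library construction) and a right mode near the
genome-wide density (freely disrupted genes). The two modes are modeled as
a two-component gamma mixture fit by expectation-maximization, and each
gene is called by the log2 likelihood-ratio of the two components at its
index. Genes between the thresholds are left ambiguous rather than forced
into either class.

Gamma densities vanish at zero while truly essential genes have an index
of exactly zero, so all indices are evaluated at ``index + floor`` with a
small floor (half the reciprocal of the longest gene by default) — the
left component then behaves as a point-mass-tolerant spike.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, special, stats as sps

DEFAULT_LLR_LO = -2.0
DEFAULT_LLR_HI = 2.0
_SHAPE_LO, _SHAPE_HI = 1e-2, 1e6


class DegenerateFitError(RuntimeError):
    """EM collapsed (unimodal data, pi -> 0 or 1); fall back to a fixed
    insertion-index threshold instead of the mixture call."""


@dataclass(frozen=True)
class EssentialityModel:
    """Two-gamma mixture over (floored) insertion indices.

    Component 0 (weight ``pi``) is the low-index, essential component;
    component 1 the permissive one. Components are always ordered by
    increasing mean.
    """

    pi: float
    shape0: float
    scale0: float
    shape1: float
    scale1: float
    log_likelihood: float
    n_genes: int
    floor: float

    @property
    def mean0(self) -> float:
        return self.shape0 * self.scale0

    @property
    def mean1(self) -> float:
        return self.shape1 * self.scale1

    def log2_likelihood_ratio(self, index: float | np.ndarray) -> float | np.ndarray:
        """log2 of (essential-component odds) at the given insertion index."""
        y = np.asarray(index, dtype=float) + self.floor
        l0 = sps.gamma.logpdf(y, self.shape0, scale=self.scale0) + np.log(self.pi)
        l1 = sps.gamma.logpdf(y, self.shape1, scale=self.scale1) + np.log1p(-self.pi)
        out = (l0 - l1) / np.log(2.0)
        return float(out) if np.isscalar(index) else out


@dataclass(frozen=True)
class EssentialityCall:
    gene_id: str
    log2_likelihood_ratio: float
    call: str  # essential | nonessential | ambiguous


def _weighted_gamma_mle(y: np.ndarray, w: np.ndarray) -> tuple[float, float]:
    """Weighted gamma MLE via the digamma equation log(s)-psi(s)=log(m)-mlog."""
    wsum = w.sum()
    m = float(np.dot(w, y) / wsum)
    mlog = float(np.dot(w, np.log(y)) / wsum)
    d = np.log(m) - mlog  # >= 0 by Jensen; 0 only for a point mass
    if d <= 1e-12:
        shape = _SHAPE_HI
    else:
        # initial Minka approximation, then safeguarded root solve
        s0 = (3 - d + np.sqrt((d - 3) ** 2 + 24 * d)) / (12 * d)
        s0 = float(np.clip(s0, _SHAPE_LO, _SHAPE_HI))
        f = lambda s: np.log(s) - special.digamma(s) - d
        try:
            lo, hi = s0 / 10, s0 * 10
            while f(lo) < 0 and lo > _SHAPE_LO:
                lo /= 10
            while f(hi) > 0 and hi < _SHAPE_HI:
                hi *= 10
            lo, hi = max(lo, _SHAPE_LO), min(hi, _SHAPE_HI)
            shape = float(optimize.brentq(f, lo, hi)) if f(lo) > 0 > f(hi) else s0
        except ValueError:
            shape = s0
    shape = float(np.clip(shape, _SHAPE_LO, _SHAPE_HI))
    return shape, m / shape


def fit_essentiality_mixture(
    indices,
    seed: int = 0,
    floor: float | None = None,
    tol: float = 1e-8,
    patience: int = 3,
    max_iter: int = 2000,
) -> EssentialityModel:
    """Fit the two-gamma mixture to per-gene insertion indices by EM.

    ``floor`` should be ``1 / (2 * max gene length)`` so that a gene with a
    single insertion still clears it; when None, half the smallest positive
    index is used. Convergence: log-likelihood improvement below ``tol``
    for ``patience`` consecutive iterations. Deterministic for fixed seed.
    """
    x = np.asarray(indices, dtype=float)
    if x.size < 100:
        raise ValueError("need at least 100 genes to fit the mixture")
    if (x < 0).any():
        raise ValueError("insertion indices must be >= 0")
    if np.ptp(x) == 0:
        raise DegenerateFitError("all insertion indices identical; use a threshold")
    if floor is None:
        positive = x[x > 0]
        floor = float(positive.min()) / 2 if positive.size else 1e-6
    y = x + floor
    logy = np.log(y)

    # deterministic 2-means initialization on log indices
    rng = np.random.default_rng(seed)
    c_lo, c_hi = np.quantile(logy, [0.05, 0.75])
    if c_lo == c_hi:
        c_lo, c_hi = logy.min(), logy.max()
    for _ in range(50):
        assign = np.abs(logy - c_lo) <= np.abs(logy - c_hi)
        if assign.all() or not assign.any():
            assign = logy <= np.median(logy)
        new_lo, new_hi = logy[assign].mean(), logy[~assign].mean()
        if new_lo == c_lo and new_hi == c_hi:
            break
        c_lo, c_hi = new_lo, new_hi
    r0 = np.where(assign, 0.98, 0.02) + rng.uniform(-1e-3, 1e-3, size=x.size)

    loglik_prev = -np.inf
    stable = 0
    for _ in range(max_iter):
        # M-step
        pi = float(np.clip(r0.mean(), 1e-6, 1 - 1e-6))
        shape0, scale0 = _weighted_gamma_mle(y, r0)
        shape1, scale1 = _weighted_gamma_mle(y, 1 - r0)
        # E-step
        l0 = sps.gamma.logpdf(y, shape0, scale=scale0) + np.log(pi)
        l1 = sps.gamma.logpdf(y, shape1, scale=scale1) + np.log1p(-pi)
        m = np.maximum(l0, l1)
        norm = m + np.log(np.exp(l0 - m) + np.exp(l1 - m))
        loglik = float(norm.sum())
        r0 = np.exp(l0 - norm)
        if loglik - loglik_prev < tol:
            stable += 1
            if stable >= patience:
                break
        else:
            stable = 0
        loglik_prev = loglik

    if pi < 1e-3 or pi > 1 - 1e-3:
        raise DegenerateFitError(
            f"mixture collapsed (pi={pi:.2g}); data look unimodal — "
            "fall back to a fixed insertion-index threshold"
        )
    mean_a, mean_b = shape0 * scale0, shape1 * scale1
    if mean_a > mean_b:  # order components by increasing mean
        pi = 1 - pi
        shape0, scale0, shape1, scale1 = shape1, scale1, shape0, scale0
        mean_a, mean_b = mean_b, mean_a
    # essential and permissive modes are orders of magnitude apart in real
    # libraries; overlapping components mean the data carry no second mode
    if mean_b < 10 * mean_a:
        raise DegenerateFitError(
            f"component means not separated ({mean_a:.3g} vs {mean_b:.3g}); "
            "data look unimodal — fall back to a fixed insertion-index threshold"
        )
    if not np.isfinite(loglik):
        raise DegenerateFitError("non-finite log-likelihood")
    return EssentialityModel(
        pi=pi,
        shape0=shape0,
        scale0=scale0,
        shape1=shape1,
        scale1=scale1,
        log_likelihood=loglik,
        n_genes=int(x.size),
        floor=floor,
    )


def call_essentiality(
    index: float,
    model: EssentialityModel,
    llr_lo: float = DEFAULT_LLR_LO,
    llr_hi: float = DEFAULT_LLR_HI,
    gene_id: str = "",
) -> EssentialityCall:
    """Classify one gene from its insertion index under the fitted mixture."""
    if not llr_lo < llr_hi:
        raise ValueError("llr_lo must be below llr_hi")
    llr = float(model.log2_likelihood_ratio(index))
    if llr >= llr_hi:
        call = "essential"
    elif llr <= llr_lo:
        call = "nonessential"
    else:
        call = "ambiguous"
    return EssentialityCall(gene_id=gene_id, log2_likelihood_ratio=llr, call=call)


def essentiality_table(
    gene_ids,
    indices,
    model: EssentialityModel,
    llr_lo: float = DEFAULT_LLR_LO,
    llr_hi: float = DEFAULT_LLR_HI,
) -> pd.DataFrame:
    calls = [
        call_essentiality(idx, model, llr_lo, llr_hi, gene_id=g)
        for g, idx in zip(gene_ids, indices)
    ]
    return pd.DataFrame(
        {
            "gene_id": [c.gene_id for c in calls],
            "insertion_index": list(indices),
            "llr": [c.log2_likelihood_ratio for c in calls],
            "call": [c.call for c in calls],
        }
    )


def write_essentiality(df: pd.DataFrame, path: str | os.PathLike) -> None:
    df.to_csv(path, sep="\t", index=False)
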