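"""Hypergeometric term enrichment of significant gene sets.

Given a gene -> term annotation map and a background universe (all
annotated genes by default), each term is tested for over-representation
in a significant gene set with the one-sided hypergeometric upper tail:
p = P[X >= k], X ~ Hypergeom(N population, K term members, n draws).
The significance threshold is inclusive (p <= alpha, default 0.005).
No multiple-testing correction is applied to enrichment p-values.
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass

import pandas as pd
from scipy import stats as sps

DEFAULT_ENRICH_ALPHA = 0.005


@dataclass
class TermMap:
    terms: dict[str, frozenset[str]]
    background: frozenset[str]

    def __post_init__(self) -> None:
        self.terms = {t: frozenset(g) for t, g in self.terms.items()}
        self.background = frozenset(self.background)
        for term, genes in self.terms.items():
            if not genes <= self.background:
                raise ValueError(f"term {term!r} contains genes outside the background")

    @classmethod
    def from_tsv(
        cls, path: str | os.PathLike, background=None
    ) -> "TermMap":
        """Load a 2-column TSV (gene_id, term_id), one pair per line.

        With no explicit background, the union of annotated genes is used.
        """
        df = pd.read_csv(
            path, sep="\t", header=None, names=["gene_id", "term_id"], comment="#"
        )
        terms: dict[str, set[str]] = {}
        for r in df.itertuples():
            terms.setdefault(str(r.term_id), set()).add(str(r.gene_id))
        bg = (
            frozenset(background)
            if background is not None
            else frozenset(df["gene_id"].astype(str))
        )
        return cls({t: frozenset(g) for t, g in terms.items()}, bg)


@dataclass(frozen=True)
class EnrichmentResult:
    term_id: str
    k: int  # significant genes carrying the term
    n: int  # size of the significant set
    K: int  # background genes carrying the term
    N: int  # background size
    p_value: float
    significant: bool


def enrich(
    sig_genes, term_map: TermMap, alpha: float = DEFAULT_ENRICH_ALPHA
) -> list[EnrichmentResult]:
    """Hypergeometric upper-tail enrichment of every term, sorted by p."""
    sig = frozenset(sig_genes)
    if not sig <= term_map.background:
        raise ValueError("significant genes must be a subset of the background")
    N = len(term_map.background)
    n = len(sig)
    out: list[EnrichmentResult] = []
    for term, members in sorted(term_map.terms.items()):
        K = len(members)
        if K == 0:
            warnings.warn(f"term {term!r} has no background genes; skipped")
            continue
        k = len(sig & members)
        p = float(sps.hypergeom.sf(k - 1, N, K, n))  # P[X >= k]
        out.append(
            EnrichmentResult(
                term_id=term,
                k=k,
                n=n,
                K=K,
                N=N,
                p_value=min(p, 1.0),
                significant=p <= alpha,
            )
        )
    out.sort(key=lambda r: (r.p_value, r.term_id))
    return out


def enrichment_frame(results: list[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "term_id": [r.term_id for r in results],
            "k": [r.k for r in results],
            "n": [r.n for r in results],
            "K": [r.K for r in results],
            "N": [r.N for r in results],
            "p_value": [r.p_value for r in results],
            "significant": [r.significant for r in results],
        }
    )


def write_enrichment(results: list[EnrichmentResult], path: str | os.PathLike) -> None:
    enrichment_frame(results).to_csv(path, sep="\t", index=False)
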