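"""Competition-assay selection rates from colony counts.

A mutant strain R and a wild-type competitor V are mixed 1:1, stressed,
and plated at time zero and time t. The selection rate

    r = ln(Rt / R0) - ln(Vt / V0)

is the relative competitive index: 0 for neutral competition, negative
when the mutant is out-competed. A mutant eradicated by the stress
(Rt = 0) has an undefined rate; by default it is flagged rather than
imputed, since "no survivors" is a qualitative outcome, but a 0.5
pseudocount policy is available for plotting.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass

import pandas as pd

ZERO_POLICIES = ("flag", "pseudocount")


@dataclass(frozen=True)
class CompetitionCounts:
    """Colony counts (CFU): mutant R and wild type V at time 0 and time t."""

    r0: float
    rt: float
    v0: float
    vt: float

    def __post_init__(self) -> None:
        if min(self.r0, self.rt, self.v0, self.vt) < 0:
            raise ValueError("colony counts must be >= 0")


@dataclass(frozen=True)
class SelectionRate:
    r: float  # nan when undefined
    defined: bool
    pseudo_applied: bool


def selection_rate(c: CompetitionCounts, zero_policy: str = "flag") -> SelectionRate:
    """r = ln(Rt/R0) - ln(Vt/V0) with an explicit zero-survivor policy."""
    if zero_policy not in ZERO_POLICIES:
        raise ValueError(f"zero_policy must be one of {ZERO_POLICIES}")
    if c.r0 == 0 or c.v0 == 0:
        raise ValueError("no baseline: R0 and V0 must be positive")
    r0, rt, v0, vt = c.r0, c.rt, c.v0, c.vt
    pseudo = False
    if rt == 0 or vt == 0:
        if zero_policy == "flag":
            return SelectionRate(r=float("nan"), defined=False, pseudo_applied=False)
        r0, rt, v0, vt = r0 + 0.5, rt + 0.5, v0 + 0.5, vt + 0.5
        pseudo = True
    r = math.log(rt / r0) - math.log(vt / v0)
    return SelectionRate(r=r, defined=True, pseudo_applied=pseudo)


def selection_rates_from_csv(
    path: str | os.PathLike, zero_policy: str = "flag"
) -> pd.DataFrame:
    """Per-replicate and per-strain mean selection rates from a long CSV.

    Expected columns: strain, timepoint, replicate, R0, Rt, V0, Vt.
    """
    df = pd.read_csv(path)
    required = {"strain", "timepoint", "replicate", "R0", "Rt", "V0", "Vt"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"colony-count table missing columns: {sorted(missing)}")
    rates = []
    for row in df.itertuples():
        sr = selection_rate(
            CompetitionCounts(row.R0, row.Rt, row.V0, row.Vt), zero_policy=zero_policy
        )
        rates.append(sr.r if sr.defined else float("nan"))
    df = df.assign(selection_rate=rates)
    means = (
        df.groupby(["strain", "timepoint"], sort=True)["selection_rate"]
        .mean()
        .rename("mean_selection_rate")
    )
    return df.merge(means, on=["strain", "timepoint"])
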