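"""Fitness core: exact test vs independent oracles, normalization, gate, sets."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from tnfit.fitness import (
    TimepointClassification,
    bonferroni,
    classify_timepoints,
    fitness_table,
    gate_significance,
    log2_fold_change,
    nb_exact_test,
    normalize_and_dispersion,
    significant_genes,
)


# ---------------------------------------------------------------- oracles

def nb_logpmf(k: int, size: float, mean: float) -> float:
    """NB log pmf via lgamma — independent of scipy's implementation."""
    p = size / (size + mean)
    return (
        math.lgamma(k + size) - math.lgamma(size) - math.lgamma(k + 1)
        + size * math.log(p) + k * math.log1p(-p)
    )


def exact_test_oracle(c: int, t: int, n_c: int, n_t: int, phi: float) -> float:
    """Exhaustive enumeration of all splits of the pooled total."""
    total = c + t
    if total == 0:
        return 1.0
    if phi == 0.0:
        probs = [
            math.exp(
                math.lgamma(total + 1) - math.lgamma(k + 1) - math.lgamma(total - k + 1)
                + k * math.log(n_c / (n_c + n_t)) + (total - k) * math.log(n_t / (n_c + n_t))
            )
            for k in range(total + 1)
        ]
    else:
        m = total / (n_c + n_t)
        probs = [
            math.exp(
                nb_logpmf(k, n_c / phi, n_c * m) + nb_logpmf(total - k, n_t / phi, n_t * m)
            )
            for k in range(total + 1)
        ]
    z = sum(probs)
    p_obs = probs[c]
    return sum(p for p in probs if p <= p_obs * (1 + 1e-9)) / z


class TestExactTest:
    def test_equal_counts_give_p_one(self):
        assert nb_exact_test([50, 50], [50, 50], phi=0.0) == pytest.approx(1.0, abs=1e-9)
        assert nb_exact_test([50, 50], [50, 50], phi=0.3) == pytest.approx(1.0, abs=1e-9)

    def test_total_six_matches_seven_split_enumeration(self):
        """total=6, phi=0, equal sizes: enumeration over Binomial(6, 1/2)."""
        for c in range(7):
            t = 6 - c
            expected = exact_test_oracle(c, t, 1, 1, 0.0)
            assert nb_exact_test([c], [t], phi=0.0) == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("phi", [0.0, 0.3])
    def test_matches_enumeration_oracle_all_totals_to_30(self, phi):
        rng = np.random.default_rng(1)
        for total in range(0, 31):
            c = int(rng.integers(0, total + 1)) if total else 0
            t = total - c
            got = nb_exact_test([c], [t], phi=phi)
            want = exact_test_oracle(c, t, 1, 1, phi)
            assert got == pytest.approx(want, abs=1e-12), (c, t, phi)

    def test_phi_zero_reduces_to_exact_binomial(self):
        """Against scipy's binomial test for all totals <= 50."""
        rng = np.random.default_rng(2)
        for total in range(1, 51):
            c = int(rng.integers(0, total + 1))
            t = total - c
            ours = nb_exact_test([c], [t], phi=0.0)
            ref = sps.binomtest(c, total, 0.5).pvalue
            assert ours == pytest.approx(ref, abs=1e-10), (c, t)

    def test_unequal_replicate_numbers(self):
        # 2 control vs 1 treated replicate: null split is Binomial(T, 2/3)
        got = nb_exact_test([5, 7], [3], phi=0.0)
        want = exact_test_oracle(12, 3, 2, 1, 0.0)
        assert got == pytest.approx(want, abs=1e-12)

    def test_library_size_equalization(self):
        # equal explicit sizes behave like no sizes at all, and a common
        # rescaling of every library size is a no-op
        base = nb_exact_test([10, 12], [30, 28], phi=0.1)
        equal = nb_exact_test([10, 12], [30, 28], [100.0] * 2, [100.0] * 2, phi=0.1)
        rescaled = nb_exact_test([10, 12], [30, 28], [700.0] * 2, [700.0] * 2, phi=0.1)
        assert equal == pytest.approx(base, abs=1e-12)
        assert rescaled == pytest.approx(base, abs=1e-12)
        # a treated library sequenced twice as deep with doubled counts gives
        # the same normalized rates, hence a similar (not wildly different) p
        scaled = nb_exact_test([10, 12], [60, 56], [100.0] * 2, [200.0] * 2, phi=0.1)
        assert 0.0 < scaled < 5 * base

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(
        c=st.integers(min_value=0, max_value=60),
        t=st.integers(min_value=0, max_value=60),
        phi=st.sampled_from([0.0, 0.1, 0.5]),
    )
    def test_antisymmetry_property(self, c, t, phi):
        """Swapping conditions leaves the two-sided p unchanged."""
        p1 = nb_exact_test([c], [t], phi=phi)
        p2 = nb_exact_test([t], [c], phi=phi)
        assert p1 == pytest.approx(p2, rel=1e-9, abs=1e-12)
        assert 0.0 <= p1 <= 1.0

    def test_negative_phi_rejected(self):
        with pytest.raises(ValueError):
            nb_exact_test([1], [2], phi=-0.1)


class TestLog2FoldChange:
    def test_equal_counts_give_zero(self):
        assert log2_fold_change([100, 100], [100, 100]) == 0.0

    def test_four_fold_change_large_counts(self):
        lfc = log2_fold_change([1000, 1000], [4000, 4000])
        assert lfc == pytest.approx(2.0, abs=0.01)

    def test_zero_treated_with_prior(self):
        lfc = log2_fold_change([100], [0], prior_count=0.5)
        assert lfc == pytest.approx(math.log2(0.5 / 100.5), abs=1e-12)

    def test_swap_negates_exactly(self):
        a = log2_fold_change([10, 20], [35, 45])
        b = log2_fold_change([35, 45], [10, 20])
        assert a == pytest.approx(-b, abs=1e-12)


class TestBonferroni:
    @pytest.mark.parametrize(
        "p,n,expected", [(0.001, 10, 0.01), (0.0005, 4000, 1.0), (0.0, 17, 0.0)]
    )
    def test_values(self, p, n, expected):
        assert bonferroni(p, n) == pytest.approx(expected)

    def test_adjusted_never_below_raw(self):
        for p in (0.0, 1e-6, 0.02, 1.0):
            assert bonferroni(p, 7) >= p


class TestGate:
    @pytest.mark.parametrize(
        "lfc,adj_p,expected",
        [
            (-3.323, 1.13e-27, "loss"),   # strong depletion, tiny p
            (-0.961, 0.0026, "ns"),       # fractionally below the magnitude cut
            (-1.061, 0.0041, "loss"),     # just inside on both axes
            (8.392, 5.06e-134, "gain"),   # strong enrichment
            (1.5, 0.01, "ns"),            # p above threshold
            (1.0, 1e-10, "ns"),           # magnitude must strictly exceed 1
            (2.0, 0.005, "ns"),           # p must be strictly below alpha
        ],
    )
    def test_strict_gate_semantics(self, lfc, adj_p, expected):
        assert gate_significance(lfc, adj_p) == expected

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        lfc=st.floats(-10, 10, allow_nan=False),
        adj_p=st.floats(0, 1, allow_nan=False),
    )
    def test_ns_iff_inside_gate_region(self, lfc, adj_p):
        cls = gate_significance(lfc, adj_p)
        if abs(lfc) <= 1 or adj_p >= 0.005:
            assert cls == "ns"
        else:
            assert cls == ("loss" if lfc < 0 else "gain")


class TestNormalization:
    def test_identical_samples_zero_dispersion(self):
        counts = pd.DataFrame({"a": [10, 20, 30], "b": [10, 20, 30]})
        norm = normalize_and_dispersion(counts, {"a": "control", "b": "control"})
        assert norm.size_factors["a"] == norm.size_factors["b"]
        assert norm.dispersion == 0.0

    def test_moment_estimator_recovers_alpha(self):
        """NB replicates with alpha=0.3 at high depth: phi within +/-0.1."""
        rng = np.random.default_rng(6)
        mu = rng.gamma(2.0, 125.0, size=4000)  # mean depth ~250/gene
        size = 1 / 0.3

        def draw():
            return rng.negative_binomial(size, size / (size + mu))

        counts = pd.DataFrame({"c1": draw(), "c2": draw(), "t1": draw(), "t2": draw()})
        design = {"c1": "control", "c2": "control", "t1": "treated", "t2": "treated"}
        norm = normalize_and_dispersion(counts, design)
        assert abs(norm.dispersion - 0.3) <= 0.1

    def test_scaling_one_library_changes_only_its_size_factor(self):
        rng = np.random.default_rng(8)
        base = rng.poisson(100, size=500)
        counts = pd.DataFrame({"c1": base, "c2": base, "t1": base, "t2": 2 * base})
        design = {"c1": "control", "c2": "control", "t1": "treated", "t2": "treated"}
        norm = normalize_and_dispersion(counts, design)
        assert norm.size_factors["t2"] == pytest.approx(2 * norm.size_factors["t1"])
        assert norm.dispersion == pytest.approx(0.0, abs=1e-6)

    def test_zero_total_sample_rejected(self):
        counts = pd.DataFrame({"a": [1, 2], "b": [0, 0]})
        with pytest.raises(ValueError, match="zero total"):
            normalize_and_dispersion(counts, {"a": "control", "b": "treated"})


class TestFitnessTable:
    def test_depleted_gene_called_loss(self):
        rng = np.random.default_rng(9)
        n = 200
        base = rng.poisson(500, size=(n, 4)).astype(float)
        base[0, 2:] = rng.poisson(500 * 2**-3, size=2)  # gene 0 depleted 8-fold
        counts = pd.DataFrame(base, columns=["c1", "c2", "t1", "t2"],
                              index=[f"g{i}" for i in range(n)])
        design = {"c1": "control", "c2": "control", "t1": "treated", "t2": "treated"}
        results = fitness_table(counts, design)
        assert results.loc["g0", "sig_class"] == "loss"
        assert results.loc["g0", "log2fc"] == pytest.approx(-3.0, abs=0.5)
        assert (results.drop("g0")["sig_class"] == "ns").all()

    def test_all_zero_gene_not_counted_as_test(self):
        counts = pd.DataFrame(
            {"c1": [100, 0], "c2": [100, 0], "t1": [100, 0], "t2": [100, 0]},
            index=["g1", "g2"],
        )
        design = {"c1": "control", "c2": "control", "t1": "treated", "t2": "treated"}
        results = fitness_table(counts, design)
        assert results.loc["g2", "p_value"] == 1.0
        # n_tests = 1, so g1's adjusted p equals its raw p
        assert results.loc["g1", "adj_p"] == results.loc["g1", "p_value"]

    def test_adj_p_never_below_p(self):
        rng = np.random.default_rng(10)
        counts = pd.DataFrame(
            rng.poisson(50, size=(50, 4)),
            columns=["c1", "c2", "t1", "t2"],
            index=[f"g{i}" for i in range(50)],
        )
        design = {"c1": "control", "c2": "control", "t1": "treated", "t2": "treated"}
        results = fitness_table(counts, design)
        assert (results["adj_p"] >= results["p_value"] - 1e-15).all()


class TestTimepoints:
    def test_partition(self):
        cls = classify_timepoints({"a", "b", "c"}, {"b", "c", "d"})
        assert cls == TimepointClassification(
            both=frozenset({"b", "c"}),
            early_only=frozenset({"a"}),
            late_only=frozenset({"d"}),
        )

    def test_empty_early(self):
        cls = classify_timepoints(set(), {"x", "y"})
        assert cls.both == frozenset() and cls.late_only == frozenset({"x", "y"})

    def test_identical_sets(self):
        s = {"p", "q"}
        cls = classify_timepoints(s, s)
        assert cls.both == frozenset(s)
        assert not cls.early_only and not cls.late_only

    def test_sets_are_pairwise_disjoint(self):
        cls = classify_timepoints({"a", "b"}, {"b", "c"})
        assert not (cls.both & cls.early_only)
        assert not (cls.both & cls.late_only)
        assert not (cls.early_only & cls.late_only)
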