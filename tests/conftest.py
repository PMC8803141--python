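import numpy as np
import pytest

from tnfit.genome import AnnotatedGenome, GeneModel
from tnfit.profiles import InsertionProfile
from tnfit.simulate import EffectMap, GeneEffect, generate_genome, random_effects


@pytest.fixture(scope="session")
def small_genome() -> AnnotatedGenome:
    """Deterministic 50 kb genome with 40 genes."""
    return generate_genome(50_000, 40, gc_fraction=0.5, seed=11)


@pytest.fixture(scope="session")
def small_effects(small_genome) -> EffectMap:
    return random_effects(
        small_genome, n_essential=4, n_loss=4, n_gain=2,
        loss_log2=-3.0, gain_log2=2.0, seed=11,
    )


@pytest.fixture()
def toy_genome() -> AnnotatedGenome:
    """Tiny hand-built genome for exact-arithmetic assertions."""
    rng = np.random.default_rng(7)
    seq = "".join(rng.choice(list("ACGT"), size=3000))
    genes = [
        GeneModel("geneA", 1001, 2000, "+"),
        GeneModel("geneB", 2101, 2700, "-"),
    ]
    return AnnotatedGenome("toy", seq, genes)


@pytest.fixture()
def toy_profile() -> InsertionProfile:
    return InsertionProfile(
        "s1",
        "toy",
        {(1500, "+"): 7, (1500, "-"): 2, (1700, "+"): 1, (2500, "+"): 4, (50, "-"): 3},
    )
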