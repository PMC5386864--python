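import numpy as np
import pandas as pd
import pytest

from nilqtl.genmap import GeneticMap
from nilqtl.simulate import (
    EnvSpec,
    NILGenotypes,
    QTLSpec,
    simulate_nil_population,
    simulate_phenotypes,
)


@pytest.fixture(scope="session")
def small_map() -> GeneticMap:
    """Two chromosomes, 12 markers, 160 cM."""
    rows = []
    for c, (n, length) in enumerate([(7, 90.0), (5, 70.0)], start=1):
        for i, p in enumerate(np.linspace(0, length, n)):
            rows.append((f"c{c}m{i + 1}", c, float(p)))
    return GeneticMap(pd.DataFrame(rows, columns=["marker", "chrom", "pos_cm"]))


@pytest.fixture(scope="session")
def small_genos(small_map) -> NILGenotypes:
    """Three families x 15 lines on the small map (BC2S1 for more donor)."""
    from nilqtl.simulate import PedigreeSpec

    return simulate_nil_population(
        small_map,
        family_sizes={"famA": 15, "famB": 15, "famC": 15},
        pedigree=PedigreeSpec(n_backcross=2, n_self=1),
        seed=101,
    )


@pytest.fixture(scope="session")
def library_default() -> NILGenotypes:
    """Default 961-line BC4S2 library (session-cached; ~0.3 s)."""
    return simulate_nil_population(seed=2024)


def make_plots(
    genos: NILGenotypes,
    qtl: list[QTLSpec] | None = None,
    seed: int = 0,
    trait: str = "starch",
    **env_kwargs,
) -> pd.DataFrame:
    env = EnvSpec(**env_kwargs)
    return simulate_phenotypes(genos, qtl or [], env, seed=seed, traits=[trait])
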