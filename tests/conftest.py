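import sys
from pathlib import Path

import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

sys.path.insert(0, str(Path(__file__).parent))  # make tests/oracles.py importable


def random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join("ACGT"[k] for k in rng.integers(0, 4, size=n))


@pytest.fixture
def rng():
    return np.random.default_rng(20110908)


@pytest.fixture(scope="session")
def zero_divergence_genome():
    """50 planted elements, no divergence: the exact-recovery study condition."""
    from tm1kit.simulate import plant_elements

    genome, truth, reference, regions = plant_elements(
        280_000, 50, rng_seed=42)
    return genome, truth, reference, regions


@pytest.fixture(scope="session")
def zero_divergence_result(zero_divergence_genome):
    from tm1kit.pipeline import run_analysis

    genome, truth, reference, regions = zero_divergence_genome
    result = run_analysis([genome], reference=reference, regions=regions,
                          summarize=True, bootstrap_replicates=50, seed=42)
    return result


@pytest.fixture(scope="session")
def diverged_genome():
    """200 planted elements at 5% substitution divergence."""
    from tm1kit.simulate import MutationModel, plant_elements

    genome, truth, reference, regions = plant_elements(
        1_100_000, 200, mutation=MutationModel(substitution_rate=0.05),
        rng_seed=7)
    return genome, truth, reference, regions


@pytest.fixture(scope="session")
def diverged_result(diverged_genome):
    from tm1kit.pipeline import run_analysis

    genome, truth, reference, regions = diverged_genome
    result = run_analysis([genome], reference=reference, regions=regions,
                          summarize=False)
    return result
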