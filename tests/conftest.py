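import numpy as np
import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")

BASES = "ACGT"


def random_seq(n: int, seed: int = 0) -> str:
    rng = np.random.default_rng(seed)
    return "".join(BASES[i] for i in rng.integers(0, 4, n))


def plant_substitutions(seq: str, positions, rng=None) -> str:
    """Substitute each position with a different base (deterministic shift)."""
    out = list(seq)
    for p in positions:
        out[p] = BASES[(BASES.index(out[p]) + 1) % 4]
    return "".join(out)


@pytest.fixture(scope="session")
def small_genome():
    from anispec.genome import GenomeSequence
    return GenomeSequence(
        "tiny", [("c1", random_seq(8000, seed=101)),
                 ("c2", random_seq(6000, seed=102))])
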