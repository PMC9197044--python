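import numpy as np
import pytest

from radpair import (
    GMF_UT,
    HMF_UT,
    KineticsParams,
    Nucleus,
    RadicalPairSystem,
    fadh_superoxide_pair,
)


@pytest.fixture(scope="session")
def default_kinetics() -> KineticsParams:
    """k = 2e6 s^-1, r = 2e5 s^-1 — the reference kinetics point."""
    return KineticsParams()


@pytest.fixture(scope="session")
def pair_o16() -> RadicalPairSystem:
    """H5-only flavin-superoxide pair (8-dimensional)."""
    return fadh_superoxide_pair(GMF_UT)


@pytest.fixture(scope="session")
def eig_gmf(pair_o16):
    return pair_o16.eigensystem()


@pytest.fixture(scope="session")
def eig_hmf(pair_o16):
    return pair_o16.with_field(HMF_UT).eigensystem()


def random_one_nucleus_system(rng: np.random.Generator) -> RadicalPairSystem:
    """A random 8-dimensional pair: one spin-1/2 nucleus, random HFCC and field."""
    return RadicalPairSystem(
        nuclei=(
            Nucleus(
                "n1",
                0.5,
                float(rng.uniform(-2000, 2000)),
                str(rng.choice(["A", "B"])),
            ),
        ),
        field_ut=float(rng.uniform(0, 100)),
    )


def random_kinetics(rng: np.random.Generator) -> KineticsParams:
    return KineticsParams(
        k_per_s=float(10 ** rng.uniform(4.5, 7)),
        r_per_s=float(10 ** rng.uniform(3.5, 6.5)),
    )
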