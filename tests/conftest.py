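import math

import numpy as np
import pytest

from raswiring import (
    EffectorDef,
    GtpScenario,
    SynthesisConfig,
    TissueProfile,
    generate_panel,
    generate_tissues,
)


@pytest.fixture(scope="session")
def panel():
    return generate_panel(SynthesisConfig(seed=0))


@pytest.fixture(scope="session")
def tissues(panel):
    return generate_tissues(SynthesisConfig(seed=0), panel)


@pytest.fixture(scope="session")
def profile(tissues):
    return tissues[0]


@pytest.fixture
def baseline():
    return GtpScenario.baseline()


def single_ligand_complex(r_tot: float, e_tot: float, kd: float) -> float:
    """Closed-form RE for one receptor + one ligand (smaller quadratic root).

    Evaluated in the cancellation-free form 2ab / (s + sqrt(s^2 - 4ab)),
    algebraically identical to (s - sqrt(s^2 - 4ab)) / 2.
    """
    s = r_tot + e_tot + kd
    return 2 * r_tot * e_tot / (s + math.sqrt(s * s - 4 * r_tot * e_tot))


def random_panel(rng: np.random.Generator, n_max: int = 10):
    """A small random effector panel with abundances, for oracle comparisons."""
    n = int(rng.integers(1, n_max + 1))
    effs = [
        EffectorDef(f"E{i}", int(rng.integers(1, 13)),
                    float(np.exp(rng.uniform(np.log(0.04), np.log(39.0)))))
        for i in range(n)
    ]
    abund = [float(rng.lognormal(3.0, 1.0)) for _ in range(n)]
    active = float(rng.lognormal(4.0, 1.0))
    return active, list(zip(effs, abund))


def make_profile(tissue, effectors, ras, receptors=None):
    return TissueProfile(tissue, effectors, ras, receptors or {})
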