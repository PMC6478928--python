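import warnings

import numpy as np
import pytest

from socturn.atmos14c import AtmosphericCurve, synth_bomb_curve
from socturn.synthdata import GeneratorConfig, generate_study


@pytest.fixture(scope="session")
def bomb_curve():
    return synth_bomb_curve()


@pytest.fixture(scope="session")
def flat_curve():
    """Constant pre-industrial atmosphere (Δ¹⁴C ≡ 0‰)."""
    return AtmosphericCurve(
        years=np.array([1900.0, 2020.0]), delta14c=np.zeros(2)
    )


@pytest.fixture(scope="session")
def default_study():
    """One full synthetic study at the default conditions (shared: read-only)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return generate_study(GeneratorConfig(seed=20140731))


@pytest.fixture(scope="session")
def clean_study():
    """Noise-free study without planted pathologies (exact-recovery oracle)."""
    cfg = GeneratorConfig(
        seed=42,
        sigma_ams=0.0,
        sigma_incubation=0.0,
        sigma_doc_obs=0.0,
        inject_pathologies=False,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return generate_study(cfg)
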