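import numpy as np
import pytest

from biphasekit import AssayDesign, BiphasicParams, MechanismParams

# the worked reference parameter set (hand-checkable logistic terms)
REF_PARAMS = BiphasicParams(
    PA=100.0, MA=300.0, MI=20.0, log10_EC50=-8.0, log10_IC50=-6.0, p=1.0, q=2.0
)


@pytest.fixture
def ref_params() -> BiphasicParams:
    return REF_PARAMS


@pytest.fixture
def mech_params() -> MechanismParams:
    return MechanismParams(
        kcat=1.0, Km=1e-6, K_act=1e-8, alpha=10.0, K_inh=1e-6, n_act=1.0, n_inh=1.0
    )


@pytest.fixture
def clean_design() -> AssayDesign:
    """Noise-free default assay design with censoring disabled."""
    return AssayDesign(noise_cv=0.0, elisa_window=None, seed=0)


def random_params(rng: np.random.Generator) -> BiphasicParams:
    """Random valid parameter draw used by brute-force comparison tests."""
    pa = rng.uniform(0.0, 200.0)
    ma = pa + rng.uniform(0.0, 300.0)
    mi = rng.uniform(0.0, ma)
    lec = rng.uniform(-10.0, -5.0)
    lic = rng.uniform(-8.0, -3.0)
    p = rng.uniform(0.3, 4.0)
    q = rng.uniform(0.3, 4.0)
    return BiphasicParams(pa, ma, mi, lec, lic, p, q)
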