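import numpy as np
import pytest

from chankin import synthetic as syn
from chankin.channeling import MichaelisParams


@pytest.fixture(scope="session")
def acceptor_mm() -> MichaelisParams:
    """Acceptor Michaelis constants for free NADH at saturating pyruvate."""
    return MichaelisParams(vmax=140.0, km=4.4, vmax_err=20.0, km_err=0.4)


@pytest.fixture(scope="session")
def tight_spec() -> syn.GeneratorSpec:
    """Tight-binding donor (Kd 0.8 μM) study conditions."""
    return syn.GeneratorSpec(seed=11)


@pytest.fixture(scope="session")
def weak_spec() -> syn.GeneratorSpec:
    """Weak-binding donor (Kd 8.2 μM) study conditions."""
    return syn.GeneratorSpec.weak_donor(seed=11)


@pytest.fixture(scope="session")
def tight_nadh_base(tight_spec):
    """Noiseless model rates for the NADH titration, tight donor (reused across tests)."""
    return syn.steady_rates_for_design(tight_spec, "titrate_nadh_fixed_gapdh")


@pytest.fixture(scope="session")
def weak_nadh_base(weak_spec):
    return syn.steady_rates_for_design(weak_spec, "titrate_nadh_fixed_gapdh")


@pytest.fixture(scope="session")
def tight_gapdh_base(tight_spec):
    return syn.steady_rates_for_design(tight_spec, "titrate_gapdh_fixed_nadh")


@pytest.fixture(scope="session")
def weak_gapdh_base(weak_spec):
    return syn.steady_rates_for_design(weak_spec, "titrate_gapdh_fixed_nadh")


@pytest.fixture(scope="session")
def null_nadh_base(tight_spec):
    """Noiseless rates with the ternary-complex path switched off."""
    return syn.steady_rates_for_design(
        tight_spec, "titrate_nadh_fixed_gapdh", channeling=False
    )
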