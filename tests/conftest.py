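import numpy as np
import pytest

from parbcage import F_PLASMID, ParSSite, SimulationConfig, simulate_profile


@pytest.fixture(scope="session")
def f_params():
    return F_PLASMID


@pytest.fixture(scope="session")
def mc_profile_small(f_params):
    """Shared single-site Monte-Carlo profile at reduced scale
    (300 monomers x 2000 conformations) for agreement checks."""
    cfg = SimulationConfig(n_monomers=300, n_conformations=2000, seed=7)
    site = ParSSite(0, int(f_params.kuhn_bp), 0, 1.0)
    return simulate_profile([site], f_params, cfg)


@pytest.fixture(scope="session")
def mc_profile_full(f_params):
    """Full-length chain (1500 monomers) at moderate sampling for
    parameter-recovery checks over the 10-Kbp fit window."""
    cfg = SimulationConfig(n_monomers=1500, n_conformations=6000, seed=11)
    site = ParSSite(0, int(f_params.kuhn_bp), 0, 1.0)
    return simulate_profile([site], f_params, cfg)
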