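import numpy as np
import pytest

import capsulemech as cm


@pytest.fixture(scope="session")
def configs():
    return cm.default_configs()


@pytest.fixture()
def meta17():
    return cm.SampleMeta(group_id="Fb-P", animal_id=0, tech_rep=0, seed=17)


@pytest.fixture(scope="session")
def matrix_only_params():
    """Fiber-free, viscosity-free capsule: pure neo-Hookean matrix."""
    return cm.CapsuleModelParams(r_v_tan=0.0, axial_fold=0.0, f_e=0.0)


@pytest.fixture(scope="session")
def fbp_model_params():
    """Bare-device capsule configuration: 6-fold axial fibers, 12% tangential."""
    return cm.CapsuleModelParams(axial_fold=6.0)


@pytest.fixture(scope="session")
def fbpecm_model_params():
    """ECM-enveloped capsule configuration: tangential fibers only."""
    return cm.CapsuleModelParams(axial_fold=0.0)


def make_record(omega, G_storage, G_loss, gamma0=0.05, n_cycles=5,
                samples_per_cycle=64, noise_sd=0.0, rng=None):
    """Synthesize a single-frequency oscillation record with known moduli."""
    n = n_cycles * samples_per_cycle
    t = np.arange(n) * (2 * np.pi / (omega * samples_per_cycle))
    wt = omega * t
    gamma = gamma0 * np.sin(wt)
    tau = gamma0 * (G_storage * np.sin(wt) + G_loss * np.cos(wt))
    if noise_sd > 0:
        tau = tau + rng.normal(0, noise_sd, n)
    return cm.OscRecord(omega=omega, t=t, gamma=gamma, tau=tau)
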