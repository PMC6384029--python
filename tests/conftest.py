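import numpy as np
import pandas as pd
import pytest

from tripletomo import geometry, simulate
from tripletomo.simulate import SimulationConfig


@pytest.fixture(scope="session")
def model():
    """Left-handed default procentriole (rate 0.12 deg/nm)."""
    return geometry.default_procentriole(rate_deg_per_nm=0.12)


@pytest.fixture(scope="session")
def flat_model():
    """Twist-free procentriole."""
    return geometry.default_procentriole(rate_deg_per_nm=0.0)


@pytest.fixture(scope="session")
def clean_config():
    return SimulationConfig(seed=1, snr=np.inf, jitter_nm=0.0, box=40)


@pytest.fixture(scope="session")
def reference(model, clean_config):
    return simulate.make_reference(model, clean_config)


def render_labelled_stack(model, n, snr, seed, partial_every=2, box=40):
    """Stack of complete / B-partial segments with known labels and poses."""
    cfg = SimulationConfig(seed=seed, snr=snr, jitter_nm=0.0, box=box)
    rng = np.random.default_rng(seed)
    vols, labels, poses = [], [], []
    for i in range(n):
        partial = i % partial_every == 0
        k = int(rng.integers(1, model.n_fold + 1))
        zc = float(rng.integers(3, 10)) * 8.0
        pf = {"B": simulate.B_PARTIAL_PFS} if partial else None
        v = simulate.render_segment(model, k, zc, cfg, pf_subset=pf)
        v = simulate.apply_missing_wedge(v, cfg.tilt_range_deg)
        if np.isfinite(snr):
            sigma = simulate._noise_sigma(v, snr)
            v = v + rng.normal(0.0, sigma, v.shape)
        vols.append(v)
        labels.append(partial)
        poses.append({
            "phi": (model.blade_orientation_deg(zc, k) - 180.0) % 360.0,
            "theta": 0.0, "psi": 0.0, "dx": 0.0, "dy": 0.0, "dz": 0.0,
        })
    return np.stack(vols), np.array(labels), pd.DataFrame(poses), cfg


@pytest.fixture(scope="session")
def labelled_stack_snr03(model):
    """60 mixed complete/B-partial segments at SNR 0.3 with true poses."""
    return render_labelled_stack(model, 60, 0.3, seed=5)
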