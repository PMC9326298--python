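import numpy as np
import pytest

import woodstrid as ws


@pytest.fixture(scope="session")
def default_profile():
    return ws.DEFAULT_PROFILES["H_ligniperda"]


@pytest.fixture(scope="session")
def quiet_scenario():
    """Propagation condition with weak attenuation: high SNR at 5 cm."""
    return ws.PropagationScenario(
        tissue=ws.Tissue.BARK, width_cm=0.84,
        psi_db=7.560, alpha_base=0.096, c_db=25.274,
    )


@pytest.fixture(scope="session")
def chirp_recording(default_profile, quiet_scenario):
    """One synthetic recording at 5 cm with its ground truth."""
    rec, truth = ws.generate_recording(
        default_profile, quiet_scenario, z=5.0, duration_s=6.0, seed=7
    )
    return rec, truth


@pytest.fixture(scope="session")
def small_benchmark():
    """Three-setting feature benchmark, small n, for fast battery tests."""
    from woodstrid.features import normalize_features

    tables = ws.generate_feature_benchmark(
        separation_schedule={5.0: 10.0, 30.0: 2.0, 60.0: 0.0},
        n_per_species=100,
        seed=3,
    )
    return {z: normalize_features(t) for z, t in tables.items()}


def sine_spectrum(freqs, peaks):
    """PowerSpectrum with given {freq: power} peaks on a frequency axis."""
    u = np.zeros_like(np.asarray(freqs, dtype=float))
    freqs = np.asarray(freqs, dtype=float)
    for f, p in peaks.items():
        u[np.argmin(np.abs(freqs - f))] = p
    return ws.PowerSpectrum(u, freqs)
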