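import numpy as np
import pytest

from corticolink import synthetic_cortex as sc


def make_single_pair_truth(
    baseline_hz=10.0, p_direct=0.0, mu_lat_ms=4.0, sigma_lat_ms=0.3,
    gain_hz=0.0, n_m1=1,
):
    """Minimal hand-built cortex: one S1 channel, n_m1 M1 channels, fully
    controlled coupling (used for exact-value oracles)."""
    n_s1 = 1
    digit_pref = np.zeros((n_m1, 5))
    digit_pref[:, 0] = 0.5
    digit_pref -= digit_pref.mean(axis=1, keepdims=True)
    return sc.GroundTruth(
        baseline_hz=np.full(n_m1, float(baseline_hz)),
        digit_pref=digit_pref,
        vel_tuning=np.zeros((n_m1, 3)),
        p_direct=np.full((n_s1, n_m1), float(p_direct)),
        mu_lat_ms=np.full((n_s1, n_m1), float(mu_lat_ms)),
        sigma_lat_ms=np.full((n_s1, n_m1), float(sigma_lat_ms)),
        indirect_gain_hz=np.full((n_s1, n_m1), float(gain_hz)),
        task_gain={},
        s1_pf_digit=np.array([1]),
        somato_beta=1.0,
        m1_channel_ids=np.arange(n_m1),
        s1_channel_ids=np.array([1000]),
        arraymap=sc._make_arraymap(n_m1, 2, np.array([1, 2])),
    )


@pytest.fixture(scope="session")
def coupled_truth():
    return sc.make_ground_truth(n_m1=16, n_s1=8, seed=11)


@pytest.fixture(scope="session")
def coupled_session(coupled_truth):
    return sc.simulate_passive_session(coupled_truth, n_trains_per_channel=15, seed=12)


@pytest.fixture(scope="session")
def uncoupled_session():
    truth = sc.make_ground_truth(n_m1=16, n_s1=6, seed=21, coupled_fraction=0.0)
    return sc.simulate_passive_session(truth, n_trains_per_channel=15, seed=22)
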