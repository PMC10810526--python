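import numpy as np
import pytest

from presacc import madc, synthdata, vp_change


@pytest.fixture(scope="session")
def madc_observer():
    """Group-level-scale m-ADC observer: slightly lower threshold at the
    saccade target, matched sensitivities."""
    return madc.MADCParams(d=[1.1, 1.15, 1.15, 1.15],
                           t=[0.61, 0.815, 0.815, 0.815])


@pytest.fixture(scope="session")
def detection_session(madc_observer):
    return synthdata.simulate_change_detection_session(
        madc_observer, n_trials=4000, delta_theta=20.0, seed=11)


@pytest.fixture(scope="session")
def estimation_session():
    observer = synthdata.EstimationObserver()  # J̄ = (1.3, 6.4, 1.0), τ = 13
    return synthdata.simulate_estimation_session(observer, n_trials=3000,
                                                 seed=13)


@pytest.fixture(scope="session")
def both_biases_observer():
    return vp_change.VPChangeParams(variant="both_biases", j_bar=20.0, B=0.5,
                                    eta_st=0.3, eta_sa=0.6)


def simulate_vp_table(params, n_trials, delta_theta, seed):
    """5×5 contingency counts from a VP change observer."""
    rng = np.random.default_rng(seed)
    signals = rng.choice(5, size=n_trials)
    resp = vp_change.sample_responses(params, signals, delta_theta, rng)
    counts = np.zeros((5, 5))
    np.add.at(counts, (signals, resp), 1)
    return madc.ContingencyTable(counts)
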