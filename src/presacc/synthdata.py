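"""Synthetic dual-task behavioral sessions.

Generates trial tables with the statistical structure the analyses assume:
saccade cue uniform over the four quadrants; a change at each location with
probability 0.20 or no change (0.20); truncated-geometric post-cue stimulus
duration (10–210 ms in 20 ms steps); ex-Gaussian saccade latencies with a
median near 260 ms; estimation trials with independently circular-uniform
orientations and a configurable single-set / double-set / noise-mask mix.
Responses come from parameterized m-ADC or variable-precision observers, so
every downstream analysis can run end to end with no external data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import trials as trials_mod
from .circular import circ_interp_ori, wrap_orientation
from .madc import MADCParams, sample_madc_responses
from .vp_change import VPChangeParams, sample_responses as sample_vp_responses
from .vp_estimation import VPEstimationParams, sample_errors

RELATIVE_CLASSES = trials_mod.RELATIVE_CLASSES
QUADRANTS = trials_mod.QUADRANTS

#: truncated-geometric success probability over the 11 post-cue duration steps
SOA_GEOMETRIC_P = 0.3
#: ex-Gaussian saccade-latency parameters (ms): median ≈ 260 ms
LATENCY_MU, LATENCY_SIGMA, LATENCY_TAU = 220.0, 25.0, 40.0
#: generation rates for the gaze-event fields the exclusion rules act on
P_CORRECT_QUADRANT = 0.93
P_STABLE_FIXATION = 0.98


@dataclass
class EstimationObserver:
    """VP estimation observer: condition-wise mean precisions, shared τ and
    motor noise, plus the recency-bias weight applied to initial-set reports
    at the saccade target on double-set trials.

    ``j_bar_st_single`` governs single-set and noise-mask trials at the
    target, where the presaccadic benefit persists; it defaults to the
    final-set precision.
    """

    params: VPEstimationParams = field(default_factory=lambda: VPEstimationParams(
        j_bar_st_initial=1.3, j_bar_st_final=6.4, j_bar_sa=1.0, tau=13.0))
    recency_B: float = 0.5
    j_bar_st_single: float | None = None

    def __post_init__(self):
        if not 0.0 <= self.recency_B <= 1.0:
            raise ValueError("recency_B must lie in [0, 1]")
        if self.j_bar_st_single is None:
            self.j_bar_st_single = self.params.j_bar_st_final


def sample_soa(n: int, rng: np.random.Generator) -> np.ndarray:
    """Post-cue initial-set durations: geometric over {10, 30, …, 210} ms,
    truncated to the 11 steps and renormalized."""
    support = np.asarray(trials_mod.SOA_SUPPORT, dtype=float)
    k = np.arange(len(support))
    pmf = SOA_GEOMETRIC_P * (1.0 - SOA_GEOMETRIC_P) ** k
    pmf /= pmf.sum()
    return rng.choice(support, size=n, p=pmf)


def sample_saccade_latency(n: int, rng: np.random.Generator) -> np.ndarray:
    """Ex-Gaussian cue-to-saccade latencies (ms)."""
    return (rng.normal(LATENCY_MU, LATENCY_SIGMA, size=n)
            + rng.exponential(LATENCY_TAU, size=n))


def _gaze_fields(n: int, soa: np.ndarray, rng: np.random.Generator) -> dict:
    latency = sample_saccade_latency(n, rng)
    return {
        "soa_ms": soa.astype(int),
        "saccade_latency_ms": np.round(latency, 3),
        "saccade_correct_quadrant": rng.uniform(size=n) < P_CORRECT_QUADRANT,
        "fixation_stable": rng.uniform(size=n) < P_STABLE_FIXATION,
        # final set shows at soa+20 and disappears at soa+40 ms after the cue
        "saccade_onset_vs_final_offset_ms": np.round(latency - (soa + 40.0), 3),
    }


def simulate_change_detection_session(observer, n_trials: int,
                                      delta_theta: float, seed: int,
                                      session_id: int = 0,
                                      task: str = "orientation_change"
                                      ) -> pd.DataFrame:
    """One change-detection session from an m-ADC or VP-change observer.

    ``observer`` is an :class:`~presacc.madc.MADCParams` or
    :class:`~presacc.vp_change.VPChangeParams`; estimation observers are
    rejected. The change location is equally likely to be each of the four
    locations (0.20 each) or absent (0.20).
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    if isinstance(observer, EstimationObserver):
        raise TypeError("estimation observers cannot run the detection task")
    if not isinstance(observer, (MADCParams, VPChangeParams)):
        raise TypeError("observer must be MADCParams or VPChangeParams")
    rng = np.random.default_rng(seed)
    cue = rng.choice(QUADRANTS, size=n_trials)
    signals = rng.choice(5, size=n_trials)  # 0..3 relative classes, 4 = none
    if isinstance(observer, MADCParams):
        resp_idx = sample_madc_responses(observer, signals, rng)
    else:
        resp_idx = sample_vp_responses(observer, signals, delta_theta, rng)
    change_location = np.where(signals < 4,
                               np.asarray(RELATIVE_CLASSES + ("none",))[signals],
                               "none")
    response = np.array([
        "no_change" if r == 4 else
        "loc_" + trials_mod.quadrant_for_relative(c, RELATIVE_CLASSES[r])
        for c, r in zip(cue, resp_idx)])
    soa = sample_soa(n_trials, rng)
    gaze = _gaze_fields(n_trials, soa, rng)
    df = pd.DataFrame({
        "task": task,
        "session_id": session_id,
        "trial_id": np.arange(n_trials),
        "cue_location": cue,
        "change_location": change_location,
        "change_angle": np.where(signals < 4, float(delta_theta), 0.0),
        "response": response,
        **gaze,
    })
    # change event (final-set onset) relative to saccade onset, ms
    df["change_onset_vs_saccade_ms"] = np.round(
        soa + 20.0 - gaze["saccade_latency_ms"], 3)
    return df


def simulate_estimation_session(observer: EstimationObserver, n_trials: int,
                                trial_mix: dict | None = None, seed: int = 0,
                                session_id: int = 0, block_size: int = 75
                                ) -> pd.DataFrame:
    """One orientation-estimation session from a VP estimation observer.

    ``trial_mix`` gives proportions for single_set / double_set / noise_mask
    trials (default 0.4/0.6/0.0) and must sum to 1. Orientations are i.i.d.
    uniform on [0, 180). The probed set alternates block-wise; single-set and
    noise-mask trials are always probed on the initial set. On double-set
    trials the initial-set report at the cued location is attracted toward
    the final orientation with weight ``recency_B`` before encoding noise.
    """
    if trial_mix is None:
        trial_mix = {"single_set": 0.4, "double_set": 0.6, "noise_mask": 0.0}
    kinds = ("single_set", "double_set", "noise_mask")
    probs = np.array([trial_mix.get(k, 0.0) for k in kinds], dtype=float)
    if abs(probs.sum() - 1.0) > 1e-9:
        raise ValueError("trial_mix must sum to 1")
    rng = np.random.default_rng(seed)
    trial_type = rng.choice(kinds, size=n_trials, p=probs)
    cue = rng.choice(QUADRANTS, size=n_trials)
    probe = rng.choice(QUADRANTS, size=n_trials)
    initial = rng.uniform(0.0, 180.0, size=(n_trials, 4))
    final = rng.uniform(0.0, 180.0, size=(n_trials, 4))
    final[trial_type != "double_set"] = np.nan
    block_probe = np.where((np.arange(n_trials) // block_size) % 2 == 0,
                           "initial", "final")
    probed_set = np.where(trial_type == "double_set", block_probe, "initial")

    qidx = {q: i for i, q in enumerate(QUADRANTS)}
    p = observer.params
    reports = np.empty(n_trials)
    for i in range(n_trials):
        loc = qidx[probe[i]]
        at_st = probe[i] == cue[i]
        truth = initial[i, loc] if probed_set[i] == "initial" else final[i, loc]
        target = truth
        if trial_type[i] == "double_set":
            if at_st:
                if probed_set[i] == "final":
                    j_bar = p.j_bar_st_final
                else:
                    j_bar = p.j_bar_st_initial
                    target = circ_interp_ori(truth, final[i, loc],
                                             observer.recency_B)
            else:
                j_bar = p.j_bar_sa
        else:  # single set or noise mask: only the initial set carries Gabors
            j_bar = observer.j_bar_st_single if at_st else p.j_bar_sa
        if np.isinf(j_bar):
            reports[i] = wrap_orientation(target)
        else:
            err = sample_errors(j_bar, p.tau, 1, rng, kappa_m=p.kappa_m)[0]
            reports[i] = wrap_orientation(target + err)

    soa = sample_soa(n_trials, rng)
    gaze = _gaze_fields(n_trials, soa, rng)
    df = pd.DataFrame({
        "task": "estimation",
        "session_id": session_id,
        "trial_id": np.arange(n_trials),
        "cue_location": cue,
        "trial_type": trial_type,
        "block_probe": block_probe,
        "probe_location": probe,
        "probed_set": probed_set,
        "reported_orientation": np.round(reports, 4) % 180.0,
        **gaze,
    })
    for j, q in enumerate(QUADRANTS):
        df[f"initial_ori_{q}"] = np.round(initial[:, j], 4) % 180.0
        df[f"final_ori_{q}"] = np.round(final[:, j], 4) % 180.0
    return df


# re-exported table utilities: the trial-table half of this module's surface
apply_gaze_exclusion = trials_mod.apply_gaze_exclusion
build_contingency_table = trials_mod.build_contingency_table
read_trials = trials_mod.read_trials
write_trials = trials_mod.write_trials
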