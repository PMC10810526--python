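"""Trial tables: schema, relative-location geometry, CSV I/O, gaze-based
exclusion, and stimulus-response contingency tables.

One row per behavioral trial. Change locations are stored *relative to the
saccade cue* (cued / opposite / ipsilateral / contralateral / none) while cue
and response locations are stored as screen quadrants (UR, UL, LL, LR); the
contingency-table builder re-sorts responses relative to each trial's cue.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .madc import ContingencyTable

QUADRANTS = ("UR", "UL", "LL", "LR")
RELATIVE_CLASSES = ("cued", "opposite", "ipsilateral", "contralateral")
DETECTION_TASKS = ("orientation_change", "contrast_change")
SOA_SUPPORT = tuple(range(10, 211, 20))

_RIGHT = {"UR", "LR"}
_UPPER = {"UR", "UL"}

BASE_COLUMNS = [
    "task", "session_id", "trial_id", "cue_location", "soa_ms",
    "saccade_latency_ms", "saccade_correct_quadrant", "fixation_stable",
    "saccade_onset_vs_final_offset_ms",
]
DETECTION_COLUMNS = BASE_COLUMNS + [
    "change_location", "change_angle", "response", "change_onset_vs_saccade_ms",
]
ESTIMATION_COLUMNS = BASE_COLUMNS + [
    "trial_type", "block_probe", "probe_location", "probed_set",
    "reported_orientation",
] + [f"initial_ori_{q}" for q in QUADRANTS] + [f"final_ori_{q}" for q in QUADRANTS]

GAZE_COLUMNS = ["saccade_correct_quadrant", "saccade_latency_ms",
                "fixation_stable", "saccade_onset_vs_final_offset_ms"]


def relative_location(cue: str, loc: str) -> str:
    """Class of quadrant ``loc`` relative to the cued quadrant.

    opposite: diagonal; ipsilateral: same left/right hemifield;
    contralateral: mirror quadrant in the other hemifield.
    """
    if cue not in QUADRANTS or loc not in QUADRANTS:
        raise ValueError(f"unknown quadrant: {cue!r}/{loc!r}")
    if loc == cue:
        return "cued"
    same_lr = (loc in _RIGHT) == (cue in _RIGHT)
    same_ud = (loc in _UPPER) == (cue in _UPPER)
    if same_lr:
        return "ipsilateral"
    return "contralateral" if same_ud else "opposite"


def quadrant_for_relative(cue: str, rel: str) -> str:
    """Inverse of :func:`relative_location` for a given cue."""
    for q in QUADRANTS:
        if relative_location(cue, q) == rel:
            return q
    raise ValueError(f"unknown relative class {rel!r}")


def response_to_relative(cue, response) -> np.ndarray:
    """Map absolute responses (``loc_UR``.. / ``no_change``) to relative classes."""
    cue = np.asarray(cue)
    response = np.asarray(response)
    out = np.empty(len(response), dtype=object)
    for i, (c, r) in enumerate(zip(cue, response)):
        out[i] = "no_change" if r == "no_change" else relative_location(c, r[4:])
    return out


def validate_trials(trials: pd.DataFrame) -> None:
    """Strict schema check; raises ValueError naming the offending rows/columns."""
    if "task" not in trials.columns:
        raise ValueError("trial table lacks a 'task' column")
    tasks = set(trials["task"].unique())
    required = set(BASE_COLUMNS)
    if tasks & set(DETECTION_TASKS):
        required |= set(DETECTION_COLUMNS)
    if "estimation" in tasks:
        required |= set(ESTIMATION_COLUMNS)
    missing = required - set(trials.columns)
    if missing:
        raise ValueError(f"trial table missing columns: {sorted(missing)}")
    bad_soa = ~trials["soa_ms"].isin(SOA_SUPPORT)
    if bad_soa.any():
        raise ValueError(
            f"soa_ms outside the 10..210 (step 20) support at rows "
            f"{list(trials.index[bad_soa][:5])}")
    for col in [c for c in trials.columns if c.endswith(tuple(
            f"_ori_{q}" for q in QUADRANTS))]:
        vals = trials[col].dropna()
        if ((vals < 0) | (vals >= 180)).any():
            raise ValueError(f"orientations in {col} must lie in [0, 180)")


def write_trials(trials: pd.DataFrame, path) -> None:
    validate_trials(trials)
    trials.to_csv(path, index=False)


def read_trials(path) -> pd.DataFrame:
    trials = pd.read_csv(path)
    validate_trials(trials)
    return trials


def apply_gaze_exclusion(trials: pd.DataFrame,
                         max_latency_ms: float = 400.0):
    """Apply the gaze-based trial-inclusion rules.

    Keeps trials with a correct-quadrant saccade, cue-to-saccade latency within
    ``max_latency_ms``, stable fixation until saccade onset, and saccade onset
    at or after the final-set offset. Returns (kept trials, per-criterion
    exclusion counts).
    """
    missing = [c for c in GAZE_COLUMNS if c not in trials.columns]
    if missing:
        raise ValueError(f"gaze-event fields missing: {missing}")
    wrong_quadrant = ~trials["saccade_correct_quadrant"].astype(bool)
    late = trials["saccade_latency_ms"].to_numpy(dtype=float) > max_latency_ms
    unstable = ~trials["fixation_stable"].astype(bool)
    early = trials["saccade_onset_vs_final_offset_ms"].to_numpy(dtype=float) < 0
    excluded = wrong_quadrant | late | unstable | early
    report = {
        "n_input": int(len(trials)),
        "wrong_quadrant": int(wrong_quadrant.sum()),
        "late_saccade": int(late.sum()),
        "unstable_fixation": int(unstable.sum()),
        "saccade_before_final_offset": int(early.sum()),
        "n_excluded": int(excluded.sum()),
        "n_kept": int((~excluded).sum()),
    }
    return trials[~excluded].copy(), report


def build_contingency_table(trials: pd.DataFrame) -> ContingencyTable:
    """5×5 stimulus-by-response counts sorted relative to each trial's cue.

    Diagonal of rows 1–4: hits; last column of rows 1–4: misses; last row's
    first 4 columns: false alarms; bottom-right: correct rejections; remaining
    off-diagonal cells: mislocalizations.
    """
    if not trials["task"].isin(DETECTION_TASKS).all():
        raise ValueError("contingency tables are defined for detection tasks only")
    idx = {k: i for i, k in enumerate(RELATIVE_CLASSES + ("none",))}
    ridx = {k: i for i, k in enumerate(RELATIVE_CLASSES + ("no_change",))}
    rel_resp = response_to_relative(trials["cue_location"], trials["response"])
    counts = np.zeros((5, 5))
    for ch, rr in zip(trials["change_location"], rel_resp):
        counts[idx[ch], ridx[rr]] += 1
    return ContingencyTable(counts)
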