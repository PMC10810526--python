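"""End-to-end orchestration of the three analyses on a conforming trial table.

Parameters are estimated per participant and group statistics are computed on
the participant-level values (the VP estimation fit instead pools errors
across participants). Every section of the report records the seeds and
Monte-Carlo sizes it used, so re-running with the same configuration
reproduces each number exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from . import estmetrics, madc, stats, synthdata, vp_change
from .circular import signed_ori_diff
from .trials import (QUADRANTS, apply_gaze_exclusion, build_contingency_table,
                     validate_trials)


@dataclass
class PipelineConfig:
    """Single source of truth for seeds, Monte-Carlo sizes and thresholds."""

    seed: int = 0
    n_shuffles: int = 1000
    n_gof_rand: int = 200
    delta_theta: float = 20.0
    vp_n_J: int = 1000
    vp_n_xy: int = 4800
    vp_final_st_ratio: float = 6.0
    vp_tau: float = 13.0
    temporal_windows: tuple = (-175.0, -125.0, -75.0, -25.0)
    temporal_width: float = 50.0
    variants: tuple = vp_change.VARIANTS
    alpha: float = 0.05
    n_dip_boot: int = 100
    dip_subsample: int = 200

    def to_dict(self) -> dict:
        return asdict(self)


def _participants(trials: pd.DataFrame):
    if "participant" in trials.columns:
        for pid, sub in trials.groupby("participant"):
            yield pid, sub
    else:
        yield 0, trials


def run_change_detection_analysis(trials: pd.DataFrame,
                                  config: PipelineConfig | None = None) -> dict:
    """Exclusions → contingency tables → m-ADC fits → SA averaging →
    temporal windows → control analyses → permutation/BF statistics."""
    config = config or PipelineConfig()
    validate_trials(trials)
    kept, exclusion_report = apply_gaze_exclusion(trials)
    per_participant = []
    for pid, sub in _participants(kept):
        table = build_contingency_table(sub)
        params, ll = madc.fit_madc(table)
        gof_p = madc.gof_randomization(table, params, n_rand=config.n_gof_rand,
                                       seed=config.seed)
        sdt1d = madc.fit_1d_sdt_no_mislocalization(table)
        counts = table.counts
        sa_rows = counts[1:4]
        ml_toward_st = float(sa_rows[:, 0].sum() / max(sa_rows.sum(), 1))
        st_row = counts[0]
        ml_toward_sa = float(st_row[1:4].sum() / max(st_row.sum(), 1))
        windows = madc.temporal_binned_params(sub, config.temporal_windows,
                                              config.temporal_width)
        # saccade-latency controls
        lat = sub["saccade_latency_ms"].to_numpy(dtype=float)
        is_change = (sub["change_location"] != "none").to_numpy()
        mw_p = float(scipy_mannwhitney(lat[is_change], lat[~is_change]))
        # transient-locked saccade-onset unimodality (subsampled for speed)
        transient_locked = lat - sub["soa_ms"].to_numpy(dtype=float)
        if len(transient_locked) > config.dip_subsample:
            idx = np.random.default_rng(config.seed).choice(
                len(transient_locked), config.dip_subsample, replace=False)
            transient_locked = transient_locked[idx]
        dip, dip_p = stats.dip_test(transient_locked,
                                    n_boot=config.n_dip_boot,
                                    seed=config.seed)
        per_participant.append({
            "participant": pid,
            "d": params.d.tolist(), "t": params.t.tolist(),
            "c": params.c.tolist(),
            "d_toward": float(params.d[0]),
            "d_away": float(params.d[1:].mean()),
            "c_toward": float(params.c[0]),
            "c_away": float(params.c[1:].mean()),
            "log_likelihood": ll, "gof_p": gof_p,
            "sdt1d": sdt1d,
            "ml_rate_toward_st": ml_toward_st,
            "ml_rate_toward_sa": ml_toward_sa,
            "latency_change_vs_nochange_p": mw_p,
            "dip_p": dip_p,
            "windows": {c: (None if w is None else
                            {"d": w[0].d.tolist(), "c": w[0].c.tolist()})
                        for c, w in windows.items()},
        })
    df = pd.DataFrame(per_participant)
    group: dict = {"n_participants": int(len(df))}
    if len(df) >= 3:
        d_perm = stats.location_permutation_test(
            df["d_toward"], df["d_away"], n_shuffles=config.n_shuffles,
            seed=config.seed)
        c_perm = stats.location_permutation_test(
            df["c_toward"], df["c_away"], n_shuffles=config.n_shuffles,
            seed=config.seed)
        ml_perm = stats.location_permutation_test(
            df["ml_rate_toward_st"], df["ml_rate_toward_sa"],
            n_shuffles=config.n_shuffles, seed=config.seed)
        group.update({
            "d_toward_mean": float(df["d_toward"].mean()),
            "d_away_mean": float(df["d_away"].mean()),
            "c_toward_mean": float(df["c_toward"].mean()),
            "c_away_mean": float(df["c_away"].mean()),
            "d_perm_p": d_perm.p_value, "c_perm_p": c_perm.p_value,
            "mislocalization_perm_p": ml_perm.p_value,
            "d_bf_one_tailed": stats.jzs_bayes_factor(
                df["d_toward"] - df["d_away"], tail="one"),
            "c_bf_one_tailed": stats.jzs_bayes_factor(
                df["c_away"] - df["c_toward"], tail="one"),
        })
        # sensitivity and criterion across the three SA locations
        d_arr = np.vstack(df["d"].to_numpy())
        c_arr = np.vstack(df["c"].to_numpy())
        group["d_sa_kruskal_p"] = stats.kruskal_wallis(
            d_arr[:, 1], d_arr[:, 2], d_arr[:, 3])[1]
        group["c_sa_kruskal_p"] = stats.kruskal_wallis(
            c_arr[:, 1], c_arr[:, 2], c_arr[:, 3])[1]
    return {"config": config.to_dict(), "exclusion": exclusion_report,
            "per_participant": per_participant, "group": group}


def scipy_mannwhitney(a, b) -> float:
    from scipy.stats import mannwhitneyu

    if len(a) == 0 or len(b) == 0:
        return float("nan")
    return float(mannwhitneyu(a, b).pvalue)


def _estimation_error_samples(sub: pd.DataFrame):
    """Per-trial signed errors with condition labels and the biasing-stimulus
    relative orientation (final−initial for initial-set probes, converse for
    final-set probes)."""
    qidx = {q: i for i, q in enumerate(QUADRANTS)}
    loc = sub["probe_location"].map(qidx).to_numpy()
    rows_ix = np.arange(len(sub))
    initial = sub[[f"initial_ori_{q}" for q in QUADRANTS]].to_numpy()
    final = sub[[f"final_ori_{q}" for q in QUADRANTS]].to_numpy()
    probed_initial = (sub["probed_set"] == "initial").to_numpy()
    truth = np.where(probed_initial, initial[rows_ix, loc],
                     final[rows_ix, loc])
    other = np.where(probed_initial, final[rows_ix, loc],
                     initial[rows_ix, loc])
    keep = ~np.isnan(truth)
    err = estmetrics.signed_error(
        sub["reported_orientation"].to_numpy()[keep], truth[keep])
    with np.errstate(invalid="ignore"):
        rel = signed_ori_diff(other[keep], truth[keep])
    return pd.DataFrame({
        "error": err,
        "relative": rel,
        "location_class": np.where(
            (sub["probe_location"] == sub["cue_location"]).to_numpy()[keep],
            "ST", "SA"),
        "trial_type": sub["trial_type"].to_numpy()[keep],
        "probed_set": sub["probed_set"].to_numpy()[keep],
    })


def run_estimation_analysis(trials: pd.DataFrame,
                            config: PipelineConfig | None = None) -> dict:
    """MAE/precision per condition, recency/primacy bias AUCs, and the
    group-level Wilcoxon/BF statistics."""
    config = config or PipelineConfig()
    validate_trials(trials)
    kept, exclusion_report = apply_gaze_exclusion(trials)
    per_participant = []
    for pid, sub in _participants(kept):
        samples = _estimation_error_samples(sub)
        entry: dict = {"participant": pid}
        for (ttype, pset, loc), grp in samples.groupby(
                ["trial_type", "probed_set", "location_class"]):
            key = f"{ttype}_{pset}_{loc}"
            errs = grp["error"].to_numpy()
            if len(errs) >= 2:
                entry[f"mae_{key}"] = estmetrics.mae(errs)
                entry[f"precision_{key}"] = estmetrics.precision(errs)[0]
        # recency bias: initial-set probes of double-set trials
        for loc in ("ST", "SA"):
            for name, pset in (("recency", "initial"), ("primacy", "final")):
                grp = samples[(samples["trial_type"] == "double_set")
                              & (samples["probed_set"] == pset)
                              & (samples["location_class"] == loc)]
                if len(grp) >= 40:
                    curve = estmetrics.bias_curve(grp["relative"].to_numpy(),
                                                  grp["error"].to_numpy())
                    try:
                        entry[f"{name}_bias_{loc}"] = \
                            estmetrics.signed_auc_bias(curve)
                    except ValueError:
                        entry[f"{name}_bias_{loc}"] = np.nan
        per_participant.append(entry)
    df = pd.DataFrame(per_participant)
    group: dict = {"n_participants": int(len(df))}
    for col in [c for c in df.columns if c != "participant"]:
        vals = df[col].dropna().to_numpy(dtype=float)
        if len(vals) >= 3:
            group[f"{col}_mean"] = float(np.mean(vals))
            if col.startswith(("recency_bias", "primacy_bias")):
                group[f"{col}_wilcoxon_p"] = stats.wilcoxon_signed_rank(vals)[1]
                if np.std(vals) > 0:
                    group[f"{col}_bf"] = stats.jzs_bayes_factor(vals, tail="two")
    # toward-vs-away contrasts on MAE where both sides exist
    for key in ("single_set_initial", "double_set_initial", "double_set_final",
                "noise_mask_initial"):
        st, sa = f"mae_{key}_ST", f"mae_{key}_SA"
        if st in df.columns and sa in df.columns:
            both = df[[st, sa]].dropna()
            if len(both) >= 3:
                res = stats.location_permutation_test(
                    both[sa], both[st], n_shuffles=config.n_shuffles,
                    seed=config.seed)
                group[f"mae_{key}_away_minus_toward_p"] = res.p_value
    return {"config": config.to_dict(), "exclusion": exclusion_report,
            "per_participant": per_participant, "group": group}


def run_vp_model_comparison(trials: pd.DataFrame,
                            config: PipelineConfig | None = None) -> dict:
    """Fit all four VP variants per participant, with AICc, leave-session-out
    cross-validated likelihoods, GOF randomization and predicted-vs-observed
    response-proportion correlation."""
    config = config or PipelineConfig()
    validate_trials(trials)
    kept, _ = apply_gaze_exclusion(trials)
    fit_kwargs = dict(final_st_precision_ratio=config.vp_final_st_ratio,
                      tau=config.vp_tau, n_J=config.vp_n_J,
                      n_xy=config.vp_n_xy, seed=config.seed)
    per_participant = []
    for pid, sub in _participants(kept):
        table = build_contingency_table(sub)
        delta = float(np.median(
            sub.loc[sub["change_location"] != "none", "change_angle"]))
        session_tables = [build_contingency_table(s).counts
                          for _, s in sub.groupby("session_id")]
        entry: dict = {"participant": pid, "delta_theta": delta}
        counts3 = vp_change.condense_table(table)
        obs_prop = counts3 / counts3.sum(axis=1, keepdims=True)
        for variant in config.variants:
            fit = vp_change.fit_variant(table, variant, delta, **fit_kwargs)
            pred = vp_change.predict_response_distribution(
                fit.params, delta, n_J=config.vp_n_J, n_xy=config.vp_n_xy,
                seed=config.seed)
            r = float(np.corrcoef(pred.condensed.ravel(),
                                  obs_prop.ravel())[0, 1])
            entry[variant] = {
                "params": {k: getattr(fit.params, k)
                           for k in ("j_bar", "B", "eta_st", "eta_sa")},
                "log_likelihood": fit.log_likelihood,
                "aicc": fit.aicc,
                "gof_p": _vp_gof(counts3, pred.condensed, config),
                "pred_obs_r": r,
            }
            if len(session_tables) >= 2:
                entry[variant]["cv_likelihood"] = \
                    vp_change.cross_validated_likelihood(
                        session_tables, variant, delta, **fit_kwargs)
        per_participant.append(entry)
    group: dict = {"n_participants": len(per_participant)}
    for variant in config.variants:
        group[f"aicc_{variant}_median"] = float(np.median(
            [e[variant]["aicc"] for e in per_participant]))
        cvs = [e[variant].get("cv_likelihood") for e in per_participant]
        cvs = [c for c in cvs if c is not None]
        if cvs:
            group[f"cv_likelihood_{variant}_median"] = float(np.median(cvs))
    etas_st = [e["both_biases"]["params"]["eta_st"] for e in per_participant]
    etas_sa = [e["both_biases"]["params"]["eta_sa"] for e in per_participant]
    group["eta_st_median"] = float(np.median(etas_st))
    group["eta_sa_median"] = float(np.median(etas_sa))
    if len(etas_st) >= 5:
        group["eta_wilcoxon_p"] = stats.wilcoxon_signed_rank(
            np.asarray(etas_sa) - np.asarray(etas_st))[1]
    return {"config": config.to_dict(), "per_participant": per_participant,
            "group": group}


def _vp_gof(counts3: np.ndarray, probs3: np.ndarray,
            config: PipelineConfig) -> float:
    """χ² randomization goodness of fit of a condensed 3×3 table."""
    rng = np.random.default_rng(config.seed)
    expected = counts3.sum(axis=1, keepdims=True) * probs3
    expected = np.maximum(expected, 1e-6)
    obs = float(np.sum((counts3 - expected) ** 2 / expected))
    row_totals = counts3.sum(axis=1).astype(int)
    exceed = 0
    for _ in range(config.n_gof_rand):
        sim = np.vstack([rng.multinomial(n, p / p.sum())
                         for n, p in zip(row_totals, probs3)])
        stat = float(np.sum((sim - expected) ** 2 / expected))
        if stat >= obs:
            exceed += 1
    return (exceed + 1) / (config.n_gof_rand + 1)


def simulate_change_detection_cohort(n_participants: int, n_sessions: int,
                                     trials_per_session: int, observer_factory,
                                     delta_theta: float, seed: int
                                     ) -> pd.DataFrame:
    """Concatenate per-participant, per-session synthetic detection sessions.

    ``observer_factory(participant_index, rng)`` returns the observer for one
    participant (MADCParams or VPChangeParams).
    """
    rng = np.random.default_rng(seed)
    frames = []
    for pid in range(n_participants):
        observer = observer_factory(pid, rng)
        for sess in range(n_sessions):
            df = synthdata.simulate_change_detection_session(
                observer, trials_per_session, delta_theta,
                seed=int(rng.integers(2**31)), session_id=sess)
            df["participant"] = pid
            frames.append(df)
    return pd.concat(frames, ignore_index=True)


def simulate_estimation_cohort(n_participants: int, trials_per_participant: int,
                               observer_factory, seed: int,
                               trial_mix: dict | None = None) -> pd.DataFrame:
    rng = np.random.default_rng(seed)
    frames = []
    for pid in range(n_participants):
        observer = observer_factory(pid, rng)
        df = synthdata.simulate_estimation_session(
            observer, trials_per_participant, trial_mix=trial_mix,
            seed=int(rng.integers(2**31)), session_id=0)
        df["participant"] = pid
        frames.append(df)
    return pd.concat(frames, ignore_index=True)
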