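"""Reusable simulation experiments over the full pipeline.

Each function simulates data with known ground truth, runs the relevant part
of the analysis chain, and reports recovery statistics.  These are the
building blocks of the analysis scripts and the acceptance checks; problem
sizes are arguments so callers choose their scale.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd

from . import preprocess, slow_waves, spindles, stimlock, stats, tuning
from .io import EventTable, seconds_to_samples
from .simulate import CohortSpec, DEFAULT_EFFECTS, EffectSpec, NapSpec, simulate_cohort, simulate_nap


def eligible_events(events: EventTable, mask: np.ndarray, fs: float) -> EventTable:
    """Events lying fully inside the eligible sample mask."""
    df = events.df
    if len(df) == 0:
        return events
    keep = [
        bool(mask[int(r.onset * fs) : int(r.offset * fs)].all()) for _, r in df.iterrows()
    ]
    return EventTable(df[np.asarray(keep, dtype=bool)])


def _prep_nap(nap, stages=("N2",)):
    """Filter, re-reference and build the sample eligibility mask."""
    rec = nap.recording
    reref = preprocess.rereference(preprocess.bandpass(rec))
    sec = nap.hypnogram.eligible_seconds(int(reref.duration_s), stages)
    mask = seconds_to_samples(sec, rec.fs, rec.n_samples)
    return reref, mask


def spindle_recovery(
    n_naps: int = 20,
    seed: int = 0,
    snr: float = 3.0,
    duration_min: float = 8.0,
    params: spindles.SpindleParams | None = None,
    channel: str = "Cz",
) -> dict:
    """Event-level precision/recall of the spindle detector on synthetic naps
    with embedded spindles at the given SNR (N2, single channel)."""
    rng = np.random.default_rng(seed)
    params = params or spindles.SpindleParams()
    tp = fp = fn = 0
    for _ in range(n_naps):
        spec = NapSpec(
            duration_min=duration_min,
            sol_min=1.0,
            channels=(channel, "TP9", "TP10"),
            spindle_snr=snr,
        )
        nap = simulate_nap(spec, rng)
        reref, mask = _prep_nap(nap, stages=("N2",))
        det = spindles.detect_spindles(
            reref.get(channel), reref.fs, params, eligible_mask=mask, channel=channel
        )
        gt = eligible_events(nap.events.select(type="spindle"), mask, reref.fs)
        m = tuning.match_events(det, gt)
        tp, fp, fn = tp + m.tp, fp + m.fp, fn + m.fn
    res = tuning.MatchResult(tp=tp, fp=fp, fn=fn)
    return {
        "precision": res.precision,
        "recall": res.recall,
        "f1": res.f1,
        "n_true": tp + fn,
        "n_detected": tp + fp,
    }


def kc_likelihood_recovery(
    n_naps: int = 50,
    seed: int = 0,
    p_evoked: float = 0.3,
    duration_min: float = 12.0,
    channel: str = "Cz",
) -> dict:
    """ON/OFF K-complex likelihoods on stimulation naps with a planted
    evoked-K-complex probability.  Returns per-nap values and the pooled
    (eligible-S1-weighted) ON-OFF difference."""
    rng = np.random.default_rng(seed)
    windows = stimlock.WindowSpec()
    on_list, off_list, n_s1_list = [], [], []
    while len(on_list) < n_naps:
        spec = NapSpec(
            duration_min=duration_min,
            sol_min=1.0,
            condition="stimulation",
            channels=(channel, "TP9", "TP10"),
            p_evoked=p_evoked,
            stim_start_after_onset_s=10.0,
        )
        nap = simulate_nap(spec, rng)
        if nap.train is None:
            continue
        reref, _ = _prep_nap(nap)
        s1 = stimlock.select_eligible_stimuli(
            nap.train, nap.hypnogram, int(reref.duration_s), windows.kc_segment, ("N2",)
        )
        if len(s1) == 0:
            continue
        det = slow_waves.detect_slow_waves(reref.get(channel), reref.fs, channel=channel)
        on, off = stimlock.kcomplex_likelihood(det, s1, windows)
        on_list.append(on)
        off_list.append(off)
        n_s1_list.append(len(s1))
    on_arr, off_arr, w = map(np.asarray, (on_list, off_list, n_s1_list))
    n_trials = int(w.sum())
    pooled = float(((on_arr - off_arr) * w).sum() / w.sum())
    return {
        "on": on_arr,
        "off": off_arr,
        "n_s1": w,
        "n_trials": n_trials,
        "mean_diff": float((on_arr - off_arr).mean()),
        "pooled_diff": pooled,
        "binomial_ci_halfwidth": float(1.96 * np.sqrt(p_evoked * (1 - p_evoked) / n_trials)),
    }


def make_tuning_naps(
    rng: np.random.Generator,
    n_naps: int,
    snr: float,
    duration_min: float = 8.0,
    channel: str = "C4",
) -> list[tuning.TrainingNap]:
    """Naps with manual-annotation stand-ins (the planted spindles) on the
    comparison channel, packaged for the grid search."""
    naps = []
    for i in range(n_naps):
        spec = NapSpec(
            duration_min=duration_min,
            sol_min=1.0,
            channels=(channel, "TP9", "TP10"),
            spindle_snr=snr,
        )
        nap = simulate_nap(spec, rng)
        reref, mask = _prep_nap(nap, stages=("N2", "N3"))
        gt = eligible_events(nap.events.select(type="spindle"), mask, reref.fs)
        ann = gt.df.copy()
        ann["type"] = "manual_spindle"
        ann["channel"] = channel
        naps.append(
            tuning.TrainingNap(
                nap_id=f"nap{i}",
                signal=reref.get(channel),
                fs=reref.fs,
                eligible_mask=mask,
                annotations=EventTable(ann),
            )
        )
    return naps


DEFAULT_GRID = {
    "rms": [1.0, 1.275, 1.5],
    "corr": [0.4, 0.52, 0.65],
    "relpow": [0.07, 0.13, 0.2],
}


def tuning_study(
    n_seeds: int = 10,
    seed: int = 0,
    snr: float = 2.2,
    n_train: int = 5,
    n_val: int = 5,
    duration_min: float = 8.0,
    grid: dict | None = None,
) -> pd.DataFrame:
    """Grid search on a low-SNR regime (mis-calibrated for the adult default
    thresholds): per seed, tuned-vs-default pooled F1 on the training naps
    and tuned F1 on a held-out validation split."""
    grid = grid or DEFAULT_GRID
    default = spindles.SpindleParams(
        thr_rms=spindles.DEFAULT_THRESHOLDS["rms"],
        thr_corr=spindles.DEFAULT_THRESHOLDS["corr"],
        thr_relpow=spindles.DEFAULT_THRESHOLDS["relpow"],
    )
    rows = []
    for k in range(n_seeds):
        rng = np.random.default_rng(seed + 1000 * k)
        train = make_tuning_naps(rng, n_train, snr, duration_min)
        val = make_tuning_naps(rng, n_val, snr, duration_min)
        best, surface = tuning.grid_search_thresholds(
            train, grid["rms"], grid["corr"], grid["relpow"]
        )
        f1_default = tuning.pooled_counts(train, default).f1
        f1_train = tuning.pooled_counts(train, best).f1
        f1_val = tuning.pooled_counts(val, best).f1
        rows.append(
            {
                "seed": seed + 1000 * k,
                "thr_rms": best.thr_rms,
                "thr_corr": best.thr_corr,
                "thr_relpow": best.thr_relpow,
                "f1_default": f1_default,
                "f1_train": f1_train,
                "f1_val": f1_val,
            }
        )
    return pd.DataFrame(rows)


def lmm_interaction_recovery(
    n_cohorts: int = 200,
    seed: int = 0,
    beta_inter: float = -1.279,
    n_subjects: int = 35,
    outcome: str = "spindle_density",
) -> dict:
    """Interaction-estimate recovery across simulated cohorts: mean estimate
    and 95% CI coverage of the planted stimulation x reactivity effect."""
    base = DEFAULT_EFFECTS[outcome]
    eff = replace(base, beta_inter=beta_inter)
    estimates, covered = [], []
    for k in range(n_cohorts):
        spec = CohortSpec(n_subjects=n_subjects, seed=seed + k, effects={outcome: eff})
        bundle = simulate_cohort(spec)
        fit = stats.fit_lmm(bundle.feature_rows, outcome, "interaction")
        row = fit.term("condition:reactivity")
        estimates.append(row["beta"])
        covered.append(bool(row["ci_low"] <= beta_inter <= row["ci_high"]))
    est = np.asarray(estimates)
    return {
        "mean_estimate": float(est.mean()),
        "true_beta": beta_inter,
        "relative_error": float(abs(est.mean() - beta_inter) / abs(beta_inter)),
        "coverage": float(np.mean(covered)),
        "n_cohorts": n_cohorts,
    }


def lmm_type1_error(
    n_cohorts: int = 1000,
    seed: int = 0,
    n_subjects: int = 35,
    outcome: str = "spindle_density",
    alpha: float = 0.05,
) -> dict:
    """Type-I error of the interaction test under a planted null (all fixed
    effects zero)."""
    null_eff = EffectSpec(
        intercept=2.5, beta_stim=0.0, beta_react=0.0, beta_inter=0.0,
        subject_sd=0.4, resid_sd=0.4,
    )
    rejections = 0
    for k in range(n_cohorts):
        spec = CohortSpec(n_subjects=n_subjects, seed=seed + k, effects={outcome: null_eff})
        bundle = simulate_cohort(spec)
        fit = stats.fit_lmm(bundle.feature_rows, outcome, "interaction")
        if fit.term("condition:reactivity")["p"] < alpha:
            rejections += 1
    return {"type1": rejections / n_cohorts, "n_cohorts": n_cohorts, "alpha": alpha}
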