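"""Per-nap feature extraction and study-level orchestration.

``run_nap`` composes the analysis chain — band-pass filtering, linked-mastoid
re-referencing, artifact masking, band powers, slow-wave/spindle detection
and densities, macroarchitecture, and (for stimulation naps) the
stimulus-locked ON/OFF likelihoods — into one feature row per nap.
``run_study`` maps it over a cohort and produces condition-level
descriptives plus the mixed-model result table, with a machine-readable
exclusion log.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import metrics, preprocess, slow_waves, spectral, spindles, stats, stimlock
from .errors import ExclusionError, InsufficientDataError, NapscapeError
from .io import Hypnogram, Recording, StimulusTrain, seconds_to_samples

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    filter_spec: preprocess.FilterSpec = field(default_factory=preprocess.FilterSpec)
    reference: str = "linked_mastoids"
    artifact_z: float = 3.0
    use_recorded_artifacts: bool = False  # True: trust the hypnogram's mask
    sw_params: slow_waves.SWParams = field(default_factory=slow_waves.SWParams)
    spindle_params: spindles.SpindleParams = field(default_factory=spindles.SpindleParams)
    windows: stimlock.WindowSpec = field(default_factory=stimlock.WindowSpec)
    swa_roi: tuple[str, ...] = spectral.SWA_ROI
    sigma_roi: tuple[str, ...] = spectral.SIGMA_ROI
    likelihood_channel: str = "Cz"
    onset_stage: str = "any"


def run_nap(
    rec: Recording,
    hyp: Hypnogram,
    train: StimulusTrain | None = None,
    config: RunConfig | None = None,
    nap_id: str = "",
    premature_wake: bool = False,
) -> dict:
    """One nap -> one feature row (dict) with every modelled outcome.

    Raises :class:`ExclusionError` for naps that must be dropped (bad
    mastoids).  Deterministic given inputs and config.
    """
    cfg = config or RunConfig()
    filtered = preprocess.bandpass(rec, cfg.filter_spec)
    reref = preprocess.rereference(filtered, cfg.reference)

    n_seconds = int(reref.duration_s)
    if cfg.use_recorded_artifacts and hyp.artifact_mask is not None:
        art = hyp.artifact_mask[:n_seconds]
    else:
        art = preprocess.detect_artifacts(reref, hyp, z_thresh=cfg.artifact_z)
        if hyp.artifact_mask is not None:
            art = art | hyp.artifact_mask[: len(art)]

    row: dict = {"nap_id": nap_id, "condition_name": rec.meta.get("condition", "")}

    macro = metrics.macro_summary(hyp, cfg.onset_stage)
    row["nap_min"] = np.nan if premature_wake else macro.nap_min
    row["sol_min"] = macro.sol_min
    row["waso_min"] = macro.waso_min
    row["efficiency_pct"] = macro.efficiency_pct
    for st, m in macro.stage_min.items():
        row[f"min_{st}"] = m
    for st, p in macro.stage_prop.items():
        row[f"prop_{st}"] = p
    try:
        row["arousal_density"] = metrics.arousal_density(hyp, cfg.onset_stage)
    except InsufficientDataError:
        row["arousal_density"] = np.nan

    # band powers
    try:
        row["swa"] = spectral.roi_band_power(
            reref, hyp, spectral.SWA_BAND, ("N2", "N3"), cfg.swa_roi, artifact_mask=art
        ).roi_value
    except (InsufficientDataError, NapscapeError):
        row["swa"] = np.nan
    try:
        row["sigma"] = spectral.roi_band_power(
            reref, hyp, spectral.SIGMA_BAND, ("N2",), cfg.sigma_roi, artifact_mask=art
        ).roi_value
    except (InsufficientDataError, NapscapeError):
        row["sigma"] = np.nan

    # event detection and densities
    sec_n23 = hyp.eligible_seconds(n_seconds, ("N2", "N3"), artifact_mask=art)
    sec_n2 = hyp.eligible_seconds(n_seconds, ("N2",), artifact_mask=art)
    mask_n23 = seconds_to_samples(sec_n23, reref.fs, reref.n_samples)
    mask_n2 = seconds_to_samples(sec_n2, reref.fs, reref.n_samples)

    sw_events = {}
    for ch in cfg.swa_roi:
        sw_events[ch] = slow_waves.detect_slow_waves(
            reref.get(ch), reref.fs, cfg.sw_params, eligible_mask=mask_n23, channel=ch
        )
    try:
        row["sw_density"] = slow_waves.sw_density(
            sw_events, float(sec_n23.sum()), cfg.swa_roi
        )
    except InsufficientDataError:
        row["sw_density"] = np.nan

    sp_events = {}
    for ch in cfg.sigma_roi:
        sp_events[ch] = spindles.detect_spindles(
            reref.get(ch), reref.fs, cfg.spindle_params, eligible_mask=mask_n2, channel=ch
        )
    try:
        row["spindle_density"] = spindles.spindle_density(
            sp_events, float(sec_n2.sum()), cfg.sigma_roi
        )
    except InsufficientDataError:
        row["spindle_density"] = np.nan

    # stimulus-locked likelihoods (stimulation naps only)
    if train is not None and len(train.pairs):
        ch = cfg.likelihood_channel
        kc_s1 = stimlock.select_eligible_stimuli(
            train, hyp, n_seconds, cfg.windows.kc_segment, ("N2",), artifact_mask=art
        )
        sp_s1 = stimlock.select_eligible_stimuli(
            train, hyp, n_seconds, cfg.windows.sp_segment, ("N2",), artifact_mask=art
        )
        try:
            kc_events = slow_waves.detect_slow_waves(
                reref.get(ch), reref.fs, cfg.sw_params, channel=ch
            )
            on, off = stimlock.kcomplex_likelihood(kc_events, kc_s1, cfg.windows)
            row["kc_likelihood_on"], row["kc_likelihood_off"] = on, off
            row["n_eligible_s1_kc"] = len(kc_s1)
        except InsufficientDataError:
            row["kc_likelihood_on"] = row["kc_likelihood_off"] = np.nan
        try:
            spz = spindles.detect_spindles(reref.get(ch), reref.fs, cfg.spindle_params)
            on, off = stimlock.spindle_likelihood(spz, sp_s1, cfg.windows)
            row["sp_likelihood_on"], row["sp_likelihood_off"] = on, off
            row["n_eligible_s1_sp"] = len(sp_s1)
        except InsufficientDataError:
            row["sp_likelihood_on"] = row["sp_likelihood_off"] = np.nan
    return row


def run_study(
    naps: list[dict],
    subjects: pd.DataFrame,
    config: RunConfig | None = None,
    outcomes: tuple[str, ...] = ("swa", "sw_density", "sigma", "spindle_density", "nap_min"),
) -> dict:
    """Run every nap and fit the study models.

    ``naps``: dicts with keys rec, hyp, train (optional), nap_id, subject,
    condition (0/1), premature_wake (optional).  Returns a dict with the
    feature table, per-condition descriptives, the model table, and the
    exclusion log.
    """
    if subjects["subject"].nunique() < 2:
        raise InsufficientDataError("need at least 2 subjects")
    cfg = config or RunConfig()
    rows, exclusions = [], []
    for nap in naps:
        nid = nap.get("nap_id", f"{nap['subject']}-{nap.get('condition', 0)}")
        try:
            row = run_nap(
                nap["rec"],
                nap["hyp"],
                nap.get("train"),
                cfg,
                nap_id=nid,
                premature_wake=nap.get("premature_wake", False),
            )
        except ExclusionError as exc:
            exclusions.append({"nap_id": nid, "reason": exc.reason_code, "detail": str(exc)})
            log.info("nap %s excluded: %s", nid, exc)
            continue
        row["subject"] = nap["subject"]
        row["condition"] = nap.get("condition", 0)
        rows.append(row)
    features = pd.DataFrame(rows)
    if len(features) == 0:
        raise InsufficientDataError("all naps were excluded")
    features = features.merge(
        subjects[
            [c for c in ("subject", "reactivity", "sex", "age_days", "autism_likelihood",
                          "sleep_arrangement") if c in subjects.columns]
        ].rename(columns={"age_days": "age"}),
        on="subject",
        how="left",
    )

    cond_col = features["condition"].map({0: "baseline", 1: "stimulation"})
    numeric = features.select_dtypes(include=[np.number]).columns
    descriptives = features[numeric].groupby(cond_col).agg(["mean", "std", "count"])

    model_tables = []
    for outcome in outcomes:
        sub = features.dropna(subset=[outcome])
        if sub["subject"].nunique() < 2 or sub[outcome].nunique() < 3:
            exclusions.append({"nap_id": "*", "reason": "model_skipped", "detail": outcome})
            continue
        try:
            model_tables.append(stats.lmm_report(sub, outcome))
        except NapscapeError as exc:
            exclusions.append({"nap_id": "*", "reason": "model_failed", "detail": f"{outcome}: {exc}"})
    models = pd.concat(model_tables, ignore_index=True) if model_tables else pd.DataFrame()
    return {
        "features": features,
        "descriptives": descriptives,
        "models": models,
        "exclusions": pd.DataFrame(exclusions, columns=["nap_id", "reason", "detail"]),
    }
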