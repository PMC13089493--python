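"""Detector validation: event matching, F1, threshold grid search, and
comparison of dependent correlations.

Detected events are matched 1-1 to manual annotations greedily by temporal
overlap; performance is the event-level F1 (harmonic mean of precision and
recall).  Threshold tuning maximizes the pooled (micro-averaged) F1 across
training naps over a grid of (RMS, correlation, relative-power) thresholds,
with ties broken toward higher precision and then higher thresholds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ParameterError, ValidationError
from .io import EventTable
from .spindles import SigmaFeatures, SpindleParams, detect_spindles, params_with_thresholds, sigma_features


@dataclass
class MatchResult:
    tp: int
    fp: int
    fn: int
    matching_rule: str = "any-overlap greedy 1-1"

    @property
    def precision(self) -> float:
        return self.tp / (self.tp + self.fp) if (self.tp + self.fp) else 0.0

    @property
    def recall(self) -> float:
        return self.tp / (self.tp + self.fn) if (self.tp + self.fn) else 0.0

    @property
    def f1(self) -> float:
        p, r = self.precision, self.recall
        return 2 * p * r / (p + r) if (p + r) else 0.0


def _intervals(table: EventTable) -> np.ndarray:
    return table.df[["onset", "offset"]].to_numpy(float)


def match_events(
    detected: EventTable,
    annotated: EventTable,
    min_overlap_s: float = 0.0,
) -> MatchResult:
    """Greedy 1-1 matching by overlap amount; any overlap matches by default."""
    for tab in (detected, annotated):
        chans = set(tab.df["channel"].dropna())
        if len(chans) > 1:
            raise ValidationError(f"events from mixed channels: {sorted(chans)}")
    det = _intervals(detected)
    ann = _intervals(annotated)
    if len(det) == 0 or len(ann) == 0:
        return MatchResult(tp=0, fp=len(det), fn=len(ann))
    ov = np.minimum(det[:, None, 1], ann[None, :, 1]) - np.maximum(
        det[:, None, 0], ann[None, :, 0]
    )
    pairs = np.argwhere(ov > max(min_overlap_s, 0.0))
    order = np.argsort(-ov[pairs[:, 0], pairs[:, 1]], kind="stable")
    used_d: set[int] = set()
    used_a: set[int] = set()
    tp = 0
    for i, j in pairs[order]:
        if i in used_d or j in used_a:
            continue
        used_d.add(int(i))
        used_a.add(int(j))
        tp += 1
    return MatchResult(tp=tp, fp=len(det) - tp, fn=len(ann) - tp)


@dataclass
class TrainingNap:
    """One nap of the tuning corpus: comparison-channel signal, sample-level
    eligibility, and the manual annotations on that channel."""

    nap_id: str
    signal: np.ndarray
    fs: float
    eligible_mask: np.ndarray
    annotations: EventTable
    features: SigmaFeatures | None = None


def pooled_counts(naps: list[TrainingNap], params: SpindleParams) -> MatchResult:
    tp = fp = fn = 0
    for nap in naps:
        if nap.features is None:
            nap.features = sigma_features(nap.signal, nap.fs, params)
        det = detect_spindles(
            nap.signal, nap.fs, params, eligible_mask=nap.eligible_mask,
            features=nap.features,
        )
        m = match_events(det, nap.annotations)
        tp, fp, fn = tp + m.tp, fp + m.fp, fn + m.fn
    return MatchResult(tp=tp, fp=fp, fn=fn)


def grid_search_thresholds(
    naps: list[TrainingNap],
    grid_rms: list[float],
    grid_corr: list[float],
    grid_relpow: list[float],
    base_params: SpindleParams | None = None,
) -> tuple[SpindleParams, pd.DataFrame]:
    """Argmax of pooled F1 over the threshold grid.

    Returns the winning parameter set and the full F1 surface (one row per
    grid cell, with pooled and mean-per-nap F1) for audit.  Deterministic:
    ties go to higher precision, then higher thresholds.
    """
    if not naps:
        raise ParameterError("no training naps")
    if not (grid_rms and grid_corr and grid_relpow):
        raise ParameterError("empty threshold grid")
    if any(len(nap.annotations) == 0 for nap in naps) and all(
        len(nap.annotations) == 0 for nap in naps
    ):
        raise ParameterError("no annotations in the training naps")
    base = base_params or SpindleParams()
    for nap in naps:
        if nap.features is None:
            nap.features = sigma_features(nap.signal, nap.fs, base)

    rows = []
    best = None
    for r in grid_rms:
        for c in grid_corr:
            for p in grid_relpow:
                params = params_with_thresholds(base, r, c, p)
                pooled = pooled_counts(naps, params)
                per_nap = [
                    match_events(
                        detect_spindles(
                            nap.signal, nap.fs, params,
                            eligible_mask=nap.eligible_mask, features=nap.features,
                        ),
                        nap.annotations,
                    ).f1
                    for nap in naps
                ]
                rows.append(
                    {
                        "thr_rms": r,
                        "thr_corr": c,
                        "thr_relpow": p,
                        "tp": pooled.tp,
                        "fp": pooled.fp,
                        "fn": pooled.fn,
                        "precision": pooled.precision,
                        "recall": pooled.recall,
                        "f1_pooled": pooled.f1,
                        "f1_mean": float(np.mean(per_nap)),
                    }
                )
                key = (pooled.f1, pooled.precision, r, c, p)
                if best is None or key > best[0]:
                    best = (key, params)
    surface = pd.DataFrame(rows)
    return best[1], surface


def steiger_z(r_xy: float, r_xz: float, r_yz: float, n: int) -> tuple[float, float]:
    """Steiger's test for two dependent correlations sharing variable x.

    Uses Fisher-z transformed correlations and the back-transformed average
    correlation in the covariance term (Steiger 1980).  Returns (z, two-sided
    p).
    """
    from scipy import stats

    for r in (r_xy, r_xz, r_yz):
        if not -1 < r < 1:
            raise ParameterError(f"correlation {r} outside (-1, 1)")
    if n <= 3:
        raise ParameterError("n must exceed 3")
    z_xy = np.arctanh(r_xy)
    z_xz = np.arctanh(r_xz)
    rm = np.tanh(0.5 * (z_xy + z_xz))  # back-transformed average r
    num = r_yz * (1 - 2 * rm**2) - 0.5 * rm**2 * (1 - 2 * rm**2 - r_yz**2)
    s = num / (1 - rm**2) ** 2
    z = (z_xy - z_xz) * np.sqrt((n - 3) / (2 - 2 * s))
    p = 2 * stats.norm.sf(abs(z))
    return float(z), float(p)
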