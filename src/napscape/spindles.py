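"""Three-feature sigma-band sleep spindle detection.

The detector computes three per-sample feature series — the moving RMS of
the 9-16 Hz filtered signal, the moving correlation between the broadband
and sigma-filtered signals, and the relative sigma power from a short-time
spectrum — and votes each time point by counting features above their
thresholds.  The smoothed vote series (>= 2 of 3) defines candidate events;
candidates closer than 750 ms are merged and events outside 0.5-4 s are
discarded.  Thresholds default to the infant-adjusted values (RMS 1.275
sigma-units, correlation 0.52, relative power 0.13), i.e. 85%/80%/65% of the
adult defaults (1.5, 0.65, 0.2).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy.ndimage import uniform_filter1d

from .errors import AlignmentError, InsufficientDataError, ParameterError
from .io import EVENT_COLUMNS, EventTable
from .spectral import contiguous_runs

#: adult default thresholds; the infant-adjusted values are fractions of these
DEFAULT_THRESHOLDS = {"rms": 1.5, "corr": 0.65, "relpow": 0.2}
ADJUSTED_THRESHOLDS = {"rms": 1.275, "corr": 0.52, "relpow": 0.13}


@dataclass
class SpindleParams:
    sigma_band: tuple[float, float] = (9.0, 16.0)
    broad_band: tuple[float, float] = (0.2, 40.0)
    dur_range: tuple[float, float] = (0.5, 4.0)
    min_gap: float = 0.75
    thr_rms: float = ADJUSTED_THRESHOLDS["rms"]  # sigma-units above the mean
    thr_corr: float = ADJUSTED_THRESHOLDS["corr"]
    thr_relpow: float = ADJUSTED_THRESHOLDS["relpow"]
    rms_win: float = 0.3
    corr_win: float = 0.3
    stft_win: float = 2.0
    stft_step: float = 0.2
    vote_smooth: float = 0.1
    votes_required: int = 2

    def validate(self):
        if not (0 < self.dur_range[0] < self.dur_range[1]):
            raise ParameterError("invalid duration range")
        if min(self.thr_rms, self.thr_corr, self.thr_relpow) < 0:
            raise ParameterError("thresholds must be >= 0")
        if self.votes_required not in (1, 2, 3):
            raise ParameterError("votes_required must be 1, 2 or 3")


@dataclass
class SigmaFeatures:
    """Per-sample feature series on a common time grid."""

    fs: float
    rms: np.ndarray
    corr: np.ndarray
    relpow: np.ndarray


def sigma_filter(x: np.ndarray, fs: float, band=(9.0, 16.0)) -> np.ndarray:
    sos = sps.butter(4, band, btype="bandpass", fs=fs, output="sos")
    return sps.sosfiltfilt(sos, x)


def _moving_rms(x: np.ndarray, fs: float, win_s: float) -> np.ndarray:
    n = max(int(round(win_s * fs)), 1)
    return np.sqrt(uniform_filter1d(x**2, n, mode="nearest"))


def _moving_corr(x: np.ndarray, y: np.ndarray, fs: float, win_s: float) -> np.ndarray:
    n = max(int(round(win_s * fs)), 1)
    mx = uniform_filter1d(x, n, mode="nearest")
    my = uniform_filter1d(y, n, mode="nearest")
    mxy = uniform_filter1d(x * y, n, mode="nearest")
    mxx = uniform_filter1d(x * x, n, mode="nearest")
    myy = uniform_filter1d(y * y, n, mode="nearest")
    cov = mxy - mx * my
    vx = np.maximum(mxx - mx**2, 0)
    vy = np.maximum(myy - my**2, 0)
    denom = np.sqrt(vx * vy)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(denom > 0, cov / denom, 0.0)
    return np.clip(r, -1.0, 1.0)


def sigma_features(x: np.ndarray, fs: float, params: SpindleParams | None = None) -> SigmaFeatures:
    """Moving RMS, moving correlation and relative sigma power per sample."""
    params = params or SpindleParams()
    params.validate()
    x = np.asarray(x, dtype=float)
    nwin = int(round(params.stft_win * fs))
    if len(x) < nwin:
        raise InsufficientDataError(
            f"signal shorter ({len(x) / fs:.2f} s) than the STFT window ({params.stft_win} s)"
        )
    xs = sigma_filter(x, fs, params.sigma_band)
    rms = _moving_rms(xs, fs, params.rms_win)
    corr = _moving_corr(x, xs, fs, params.corr_win)

    hop = max(int(round(params.stft_step * fs)), 1)
    win = sps.get_window("hann", nwin)
    starts = np.arange(0, len(x) - nwin + 1, hop)
    freqs = np.fft.rfftfreq(nwin, d=1 / fs)
    sig_sel = (freqs >= params.sigma_band[0]) & (freqs <= params.sigma_band[1])
    tot_sel = (freqs >= params.broad_band[0]) & (freqs <= params.broad_band[1])
    frames = np.stack([x[s : s + nwin] for s in starts])
    frames = frames - frames.mean(axis=1, keepdims=True)
    spec = np.abs(np.fft.rfft(frames * win, axis=1)) ** 2
    tot = spec[:, tot_sel].sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        rel = np.where(tot > 0, spec[:, sig_sel].sum(axis=1) / tot, 0.0)
    centers = starts + nwin / 2
    t = np.arange(len(x))
    relpow = np.interp(t, centers, rel)
    return SigmaFeatures(fs=fs, rms=rms, corr=corr, relpow=np.clip(relpow, 0.0, 1.0))


def vote_candidates(
    features: SigmaFeatures,
    params: SpindleParams,
    eligible_mask: np.ndarray | None = None,
) -> list[tuple[int, int]]:
    """Maximal sample runs where the smoothed vote count reaches the quorum.

    The RMS threshold is soft: mean + thr_rms * SD of the moving-RMS series,
    with the statistics computed over eligible sleep only.
    """
    fs = features.fs
    sel = slice(None) if eligible_mask is None else np.asarray(eligible_mask, bool)
    rms_ref = features.rms[sel]
    if rms_ref.size == 0:
        raise InsufficientDataError("no eligible samples for RMS standardization")
    rms_thr = rms_ref.mean() + params.thr_rms * rms_ref.std()
    votes = (
        (features.rms > rms_thr).astype(float)
        + (features.corr > params.thr_corr)
        + (features.relpow > params.thr_relpow)
    )
    n_sm = max(int(round(params.vote_smooth * fs)), 1)
    smoothed = uniform_filter1d(votes, n_sm, mode="nearest")
    return contiguous_runs(smoothed >= params.votes_required - 1e-9)


def merge_close(runs: list[tuple[int, int]], min_gap_samples: int) -> list[tuple[int, int]]:
    merged: list[list[int]] = []
    for s, e in runs:
        if merged and s - merged[-1][1] < min_gap_samples:
            merged[-1][1] = e
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def detect_spindles(
    x: np.ndarray,
    fs: float,
    params: SpindleParams | None = None,
    eligible_mask: np.ndarray | None = None,
    channel: str = "",
    stage: str = "",
    features: SigmaFeatures | None = None,
) -> EventTable:
    """Detect sleep spindles on one channel.

    ``features`` may be precomputed (threshold changes do not require
    recomputing them, which the grid search exploits).  Events must lie fully
    inside eligible runs.
    """
    params = params or SpindleParams()
    params.validate()
    x = np.asarray(x, dtype=float)
    if eligible_mask is not None and len(eligible_mask) != len(x):
        raise AlignmentError("eligible_mask length must match the signal")
    if features is None:
        features = sigma_features(x, fs, params)
    runs = vote_candidates(features, params, eligible_mask)
    runs = merge_close(runs, int(round(params.min_gap * fs)))
    rows = []
    for s, e in runs:
        dur = (e - s) / fs
        if not (params.dur_range[0] <= dur <= params.dur_range[1]):
            continue
        if eligible_mask is not None and not eligible_mask[s:e].all():
            continue
        peak = s + int(np.argmax(features.rms[s:e]))
        rows.append(
            {
                "type": "spindle",
                "channel": channel,
                "onset": s / fs,
                "offset": e / fs,
                "neg_peak_time": peak / fs,  # time of maximal sigma RMS
                "neg_peak_amp": float(-features.rms[peak]),
                "pos_peak_amp": float(features.rms[peak]),
                "stage": stage,
            }
        )
    return EventTable(pd.DataFrame(rows, columns=list(EVENT_COLUMNS)))


def spindle_density(
    events_by_channel: dict[str, EventTable],
    eligible_seconds: float,
    roi: tuple[str, ...],
    agg: str = "median",
) -> float:
    """Per-channel spindles per eligible N2 minute, aggregated across the ROI.

    The aggregate defaults to the median (consistent with the slow-wave
    measures); ``agg="mean"`` is also supported.
    """
    if eligible_seconds <= 0:
        raise InsufficientDataError("zero eligible N2 time")
    minutes = eligible_seconds / 60.0
    dens = [len(events_by_channel.get(ch, EventTable())) / minutes for ch in roi]
    if agg == "median":
        return float(np.median(dens))
    if agg == "mean":
        return float(np.mean(dens))
    raise ParameterError(f"unknown aggregate {agg!r}")


def params_with_thresholds(
    base: SpindleParams, thr_rms: float, thr_corr: float, thr_relpow: float
) -> SpindleParams:
    return replace(base, thr_rms=thr_rms, thr_corr=thr_corr, thr_relpow=thr_relpow)
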