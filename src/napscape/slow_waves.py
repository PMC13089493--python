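"""Discrete slow-wave detection with infant-adapted amplitude criteria.

A slow wave is a negative half-wave followed by a positive half-wave of the
0.5-2 Hz band-passed signal, accepted when the negative half-wave lasts
0.3-1.5 s, the positive half-wave 0.1-1 s, the negative peak exceeds 40 µV,
the positive peak 10 µV and the peak-to-peak amplitude 75 µV.  Infant slow
waves are larger than adult ones, so there are no upper amplitude limits.
Half-wave durations are measured between consecutive zero crossings and
amplitudes on the band-passed signal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sps

from .errors import AlignmentError, InsufficientDataError, ParameterError
from .io import EVENT_COLUMNS, EventTable
from .spectral import contiguous_runs


@dataclass
class SWParams:
    band: tuple[float, float] = (0.5, 2.0)
    neg_dur: tuple[float, float] = (0.3, 1.5)
    pos_dur: tuple[float, float] = (0.1, 1.0)
    min_neg_amp: float = 40.0
    min_pos_amp: float = 10.0
    min_ptp: float = 75.0
    filter_order: int = 3

    def validate(self):
        for name, (lo, hi) in (("neg_dur", self.neg_dur), ("pos_dur", self.pos_dur)):
            if not (0 < lo < hi):
                raise ParameterError(f"invalid {name} range")
        if min(self.min_neg_amp, self.min_pos_amp, self.min_ptp) < 0:
            raise ParameterError("amplitude thresholds must be positive")


def sw_bandpass(x: np.ndarray, fs: float, params: SWParams | None = None) -> np.ndarray:
    """Zero-phase band-pass to the slow-wave band."""
    params = params or SWParams()
    sos = sps.butter(params.filter_order, params.band, btype="bandpass", fs=fs, output="sos")
    return sps.sosfiltfilt(sos, x)


def half_wave_candidates(xf: np.ndarray) -> list[tuple[int, int, int]]:
    """(neg_start, zero_up, pos_end) sample triples of the filtered signal.

    A candidate is a maximal run of negative samples followed immediately by
    a maximal run of non-negative samples, both bounded by zero crossings
    (signal start/end do not bound half-waves).
    """
    neg = xf < 0
    d = np.diff(neg.astype(int))
    down = np.flatnonzero(d == 1) + 1  # first negative sample of each neg run
    up = np.flatnonzero(d == -1) + 1  # first non-negative sample after a neg run
    out = []
    for i0 in down:
        j = up[np.searchsorted(up, i0)] if np.searchsorted(up, i0) < len(up) else None
        if j is None:
            continue
        k_idx = np.searchsorted(down, j)
        if k_idx >= len(down):
            continue  # positive half-wave not closed by a zero crossing
        out.append((int(i0), int(j), int(down[k_idx])))
    return out


def detect_slow_waves(
    x: np.ndarray,
    fs: float,
    params: SWParams | None = None,
    eligible_mask: np.ndarray | None = None,
    channel: str = "",
    stage: str = "",
    prefiltered: bool = False,
) -> EventTable:
    """Detect slow waves on one channel; events fully inside eligible runs.

    ``eligible_mask`` is per-sample; candidates touching an ineligible sample
    are discarded rather than clipped.
    """
    params = params or SWParams()
    params.validate()
    x = np.asarray(x, dtype=float)
    if eligible_mask is not None and len(eligible_mask) != len(x):
        raise AlignmentError("eligible_mask length must match the signal")
    xf = x if prefiltered else sw_bandpass(x, fs, params)

    rows = []
    for i0, j, i1 in half_wave_candidates(xf):
        neg_dur = (j - i0) / fs
        pos_dur = (i1 - j) / fs
        if not (params.neg_dur[0] <= neg_dur <= params.neg_dur[1]):
            continue
        if not (params.pos_dur[0] <= pos_dur <= params.pos_dur[1]):
            continue
        neg_seg = xf[i0:j]
        pos_seg = xf[j:i1]
        neg_peak = neg_seg.min()
        pos_peak = pos_seg.max()
        if not (-neg_peak > params.min_neg_amp):
            continue
        if not (pos_peak > params.min_pos_amp):
            continue
        if not (pos_peak - neg_peak > params.min_ptp):
            continue
        if eligible_mask is not None and not eligible_mask[i0:i1].all():
            continue
        rows.append(
            {
                "type": "slow_wave",
                "channel": channel,
                "onset": i0 / fs,
                "offset": i1 / fs,
                "neg_peak_time": (i0 + int(np.argmin(neg_seg))) / fs,
                "neg_peak_amp": float(neg_peak),
                "pos_peak_amp": float(pos_peak),
                "stage": stage,
            }
        )
    return EventTable(pd.DataFrame(rows, columns=list(EVENT_COLUMNS)))


def sw_density(
    events_by_channel: dict[str, EventTable],
    eligible_seconds: float,
    roi: tuple[str, ...],
    agg: str = "median",
) -> float:
    """Median across ROI channels of events per eligible N2+N3 minute."""
    if eligible_seconds <= 0:
        raise InsufficientDataError("zero eligible N2+N3 time")
    minutes = eligible_seconds / 60.0
    dens = [len(events_by_channel.get(ch, EventTable())) / minutes for ch in roi]
    if agg == "median":
        return float(np.median(dens))
    if agg == "mean":
        return float(np.mean(dens))
    raise ParameterError(f"unknown aggregate {agg!r}")
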