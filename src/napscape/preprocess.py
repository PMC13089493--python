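"""Filtering, re-referencing and automatic artifact masking.

The preprocessing chain is: zero-phase first-order Butterworth band-pass
0.2-40 Hz (with 50/100/150/200 Hz notches, no-ops below Nyquist/after the
low-pass), re-referencing to the linked (or contralateral) mastoids, and a
per-stage standardized log-RMS artifact detector on 1-s windows.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .errors import AlignmentError, ExclusionError, ParameterError
from .io import Hypnogram, Recording

log = logging.getLogger(__name__)

MASTOIDS = ("TP9", "TP10")  # left, right


@dataclass
class FilterSpec:
    band: tuple[float, float] = (0.2, 40.0)
    order: int = 1
    notch_freqs: tuple[float, ...] = (50.0, 100.0, 150.0, 200.0)
    notch_q: float = 30.0

    def validate(self, fs: float) -> None:
        lo, hi = self.band
        if not (0 < lo < hi):
            raise ParameterError(f"invalid band {self.band}")
        if hi >= fs / 2:
            raise ParameterError(f"band_high {hi} >= Nyquist {fs / 2}")
        if self.order < 1:
            raise ParameterError("filter order must be >= 1")


def bandpass(rec: Recording, spec: FilterSpec | None = None) -> Recording:
    """Zero-phase (forward-backward) Butterworth band-pass plus notches.

    Notch frequencies at or above Nyquist, or above the band edge, are
    skipped with a logged note (they are no-ops after the 40 Hz low-pass).
    """
    spec = spec or FilterSpec()
    spec.validate(rec.fs)
    sos = signal.butter(spec.order, spec.band, btype="bandpass", fs=rec.fs, output="sos")
    out = signal.sosfiltfilt(sos, rec.data, axis=1)
    for f0 in spec.notch_freqs:
        if f0 >= rec.fs / 2:
            log.info("skipping notch at %g Hz (>= Nyquist %g Hz)", f0, rec.fs / 2)
            continue
        if f0 > spec.band[1]:
            log.info("notch at %g Hz is above the %g Hz low-pass (retained for fidelity)",
                     f0, spec.band[1])
        b, a = signal.iirnotch(f0, spec.notch_q, fs=rec.fs)
        out = signal.filtfilt(b, a, out, axis=1)
    return rec.copy_with(out)


def rereference(
    rec: Recording,
    scheme: str = "linked_mastoids",
    mastoids: tuple[str, str] = MASTOIDS,
) -> Recording:
    """Re-reference to linked or contralateral mastoids.

    Raises :class:`ExclusionError` when a mastoid is absent or flagged bad:
    such naps are excluded from analysis rather than re-referenced with a
    degraded reference.
    """
    left, right = mastoids
    for m in (left, right):
        if m not in rec.channels:
            raise ExclusionError(f"mastoid channel {m} missing", "bad_mastoid")
        if m in rec.bad_channels:
            raise ExclusionError(f"mastoid channel {m} flagged bad", "bad_mastoid")
    m_left = rec.get(left)
    m_right = rec.get(right)
    linked = 0.5 * (m_left + m_right)

    out = np.empty_like(rec.data)
    if scheme == "linked_mastoids":
        out = rec.data - linked[None, :]
    elif scheme == "contralateral_mastoids":
        for i, ch in enumerate(rec.channels):
            side = _hemisphere(ch)
            if side == "left":
                ref = m_right
            elif side == "right":
                ref = m_left
            else:  # midline channels use the linked average
                ref = linked
            out[i] = rec.data[i] - ref
    else:
        raise ParameterError(f"unknown reference scheme {scheme!r}")
    return rec.copy_with(out, reference=scheme)


def _hemisphere(label: str) -> str:
    """10-20 convention: odd digit = left, even = right, z = midline."""
    digits = [c for c in label if c.isdigit()]
    if not digits:
        return "midline"
    return "left" if int(digits[-1]) % 2 == 1 else "right"


def detect_artifacts(
    rec: Recording,
    hyp: Hypnogram,
    win_s: float = 1.0,
    z_thresh: float = 3.0,
    channels: list[str] | None = None,
) -> np.ndarray:
    """Per-window standardized log-RMS artifact detector.

    For each ``win_s`` window the RMS is computed per channel, log-transformed
    and averaged across channels; the resulting statistic is z-scored within
    each sleep stage and the window is flagged when z > ``z_thresh``.
    Returns a boolean mask at ``win_s`` resolution.
    """
    n_win = int(rec.n_samples / (win_s * rec.fs))
    if n_win < 1:
        raise ParameterError("recording shorter than one artifact window")
    if hyp.duration_s + 30.0 < rec.duration_s:
        raise AlignmentError(
            f"hypnogram ({hyp.duration_s} s) shorter than recording ({rec.duration_s} s)"
        )
    if channels is None:
        chan_idx = [i for i, c in enumerate(rec.channels) if c not in MASTOIDS]
    else:
        chan_idx = [rec.channels.index(c) for c in channels]
    wlen = int(round(win_s * rec.fs))
    data = rec.data[chan_idx, : n_win * wlen]
    segs = data.reshape(len(chan_idx), n_win, wlen)
    rms = np.sqrt(np.mean(segs**2, axis=2))
    stat = np.log(rms + 1e-12).mean(axis=0)  # one value per window

    stage_sec = hyp.stages_per_second(int(n_win * win_s))
    win_stage = stage_sec[:: max(int(win_s), 1)][:n_win]
    mask = np.zeros(n_win, dtype=bool)
    for stage in np.unique(win_stage):
        sel = win_stage == stage
        vals = stat[sel]
        sd = vals.std()
        if sd == 0 or len(vals) < 3:
            continue
        z = (vals - vals.mean()) / sd
        mask[sel] = z > z_thresh
    return mask


def masked_seconds(mask: np.ndarray, win_s: float = 1.0) -> float:
    """Total flagged duration; equals mask sum times the window length."""
    return float(np.sum(mask) * win_s)
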