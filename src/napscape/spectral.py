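"""Welch band power over stage- and artifact-restricted sleep.

Slow-wave activity (SWA) is the absolute 0.5-2 Hz power in N2+N3; sigma
power is the 9-16 Hz power in N2.  Periodograms use 4-s Hann segments at 50%
overlap, combined by the raw median (no small-sample bias correction, so a
pure tone integrates exactly to its variance), and segments never span an
excision boundary: artifact/arousal samples are excised before segmentation
so only contiguous eligible runs contribute.  Channel values are aggregated
across the ROI with the median.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InsufficientDataError, ParameterError
from .io import Hypnogram, Recording, seconds_to_samples

SWA_BAND = (0.5, 2.0)
SIGMA_BAND = (9.0, 16.0)
SWA_ROI = ("F3", "Fz", "F4", "FC1", "FC2", "C3", "Cz", "C4", "O1", "Oz")
SIGMA_ROI = ("F3", "Fz", "F4", "FC1", "FC2", "C3", "Cz", "C4")


@dataclass
class BandPowerResult:
    band: tuple[float, float]
    per_channel: dict[str, float]
    roi_value: float
    stages_used: tuple[str, ...]
    seconds_used: float


def contiguous_runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Half-open [start, stop) index runs where mask is True."""
    mask = np.asarray(mask, dtype=bool)
    if mask.size == 0:
        return []
    padded = np.concatenate([[False], mask, [False]])
    d = np.diff(padded.astype(int))
    starts = np.flatnonzero(d == 1)
    stops = np.flatnonzero(d == -1)
    return list(zip(starts, stops))


def welch_psd(
    x: np.ndarray,
    fs: float,
    seg_s: float = 4.0,
    overlap: float = 0.5,
    eligible_mask: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """One-sided PSD in µV²/Hz, median over Hann segments at 50% overlap.

    ``eligible_mask`` is a per-sample boolean mask; segments are drawn only
    from contiguous eligible runs.  Frequency resolution is 1/seg_s.
    """
    x = np.asarray(x, dtype=float)
    nper = int(round(seg_s * fs))
    hop = max(int(round(nper * (1 - overlap))), 1)
    if eligible_mask is None:
        runs = [(0, len(x))]
    else:
        if len(eligible_mask) != len(x):
            raise ParameterError("eligible_mask length must match the signal")
        runs = contiguous_runs(eligible_mask)

    from scipy.signal import get_window

    win = get_window("hann", nper)  # periodic Hann, the Welch convention
    u = (win**2).sum() * fs  # density normalization
    periodograms = []
    for start, stop in runs:
        for s0 in range(start, stop - nper + 1, hop):
            seg = x[s0 : s0 + nper]
            seg = seg - seg.mean()
            spec = np.fft.rfft(seg * win)
            p = (spec.real**2 + spec.imag**2) / u
            p[1:] *= 2
            if nper % 2 == 0:
                p[-1] /= 2
            periodograms.append(p)
    if not periodograms:
        raise InsufficientDataError(
            f"no eligible run of at least {seg_s} s for Welch PSD"
        )
    pxx = np.median(periodograms, axis=0)
    freqs = np.fft.rfftfreq(nper, d=1 / fs)
    return freqs, pxx


def band_power(freqs: np.ndarray, psd: np.ndarray, band: tuple[float, float]) -> float:
    """Trapezoidal integral of the PSD over [low, high] (µV²)."""
    lo, hi = band
    if lo > hi:
        raise ParameterError(f"invalid band {band}")
    if lo < freqs[0] - 1e-9 or hi > freqs[-1] + 1e-9:
        raise ParameterError(f"band {band} outside PSD grid [{freqs[0]}, {freqs[-1]}]")
    if lo == hi:
        return 0.0
    sel = (freqs >= lo - 1e-9) & (freqs <= hi + 1e-9)
    return float(np.trapezoid(psd[sel], freqs[sel]))


def roi_band_power(
    rec: Recording,
    hyp: Hypnogram,
    band: tuple[float, float],
    stages: tuple[str, ...],
    roi: tuple[str, ...],
    artifact_mask: np.ndarray | None = None,
    seg_s: float = 4.0,
) -> BandPowerResult:
    """Median band power across ROI channels over eligible sleep."""
    missing = [c for c in roi if c not in rec.channels]
    if missing:
        raise ParameterError(f"ROI channels missing from recording: {missing}")
    sec_mask = hyp.eligible_seconds(
        int(rec.duration_s), stages=stages, artifact_mask=artifact_mask
    )
    if not sec_mask.any():
        raise InsufficientDataError(f"no eligible time in stages {stages}")
    sample_mask = seconds_to_samples(sec_mask, rec.fs, rec.n_samples)
    per_channel = {}
    for ch in roi:
        freqs, psd = welch_psd(rec.get(ch), rec.fs, seg_s=seg_s, eligible_mask=sample_mask)
        per_channel[ch] = band_power(freqs, psd, band)
    return BandPowerResult(
        band=band,
        per_channel=per_channel,
        roi_value=float(np.median(list(per_channel.values()))),
        stages_used=tuple(stages),
        seconds_used=float(sec_mask.sum()),
    )
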