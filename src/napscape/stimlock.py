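"""Stimulus-locked analyses: segment eligibility, evoked averages, negative
peak latency histograms, and ON/OFF event likelihoods.

Tones are presented in pairs (S1, S2): 1-s tones, 700 ms apart, with 12-18 s
between pairs.  The evoked K-complex ON window is 450-700 ms after S1 (its
negative peak latency window); the matched OFF window is -1250 to -1000 ms.
Sleep spindles are counted by event start in 0-3.4 s (ON) and -3.4-0 s (OFF)
windows; spindle segments span -4.4 to +4.4 s around S1 (1-s edge buffers),
and the K-complex detection segment spans -4.15 to +12.35 s.  Likelihood =
window event count divided by the number of eligible S1; only S1 responses
are counted (refractory period after an evoked K-complex).  All windows are
half-open [low, high) in stimulus-relative time.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InsufficientDataError, ParameterError
from .io import EventTable, Hypnogram, Recording, StimulusTrain


@dataclass
class WindowSpec:
    kc_on: tuple[float, float] = (0.450, 0.700)
    kc_off: tuple[float, float] = (-1.250, -1.000)
    sp_on: tuple[float, float] = (0.0, 3.4)
    sp_off: tuple[float, float] = (-3.4, 0.0)
    sp_segment: tuple[float, float] = (-4.4, 4.4)
    kc_segment: tuple[float, float] = (-4.15, 12.35)

    def validate(self):
        for on, off in ((self.kc_on, self.kc_off), (self.sp_on, self.sp_off)):
            len_on = on[1] - on[0]
            len_off = off[1] - off[0]
            if abs(len_on - len_off) > 1e-9:
                raise ParameterError("ON and OFF windows must have equal length")
            if max(on[0], off[0]) < min(on[1], off[1]) and not (
                on[1] <= off[0] or off[1] <= on[0]
            ):
                raise ParameterError("ON and OFF windows overlap")


def generate_stimulus_train(
    total_s: float,
    rng: np.random.Generator | int,
    tone_duration: float = 1.0,
    intra_pair_gap: float = 0.7,
    inter_pair_range: tuple[float, float] = (12.0, 18.0),
    level_db: float = 60.0,
    tone_hz: float = 225.0,
) -> StimulusTrain:
    """Paired-tone train: first S1 at t=0, i.i.d. uniform inter-pair gaps."""
    if total_s <= 20:
        raise ParameterError("total duration must exceed 20 s")
    rng = np.random.default_rng(rng) if isinstance(rng, (int, np.integer)) else rng
    span = 2 * tone_duration + intra_pair_gap
    pairs = []
    t = 0.0
    while t + span <= total_s:
        pairs.append((t, t + tone_duration + intra_pair_gap))
        t = t + span + rng.uniform(*inter_pair_range)
    return StimulusTrain(
        pairs=np.array(pairs, dtype=float).reshape(-1, 2),
        tone_duration=tone_duration,
        intra_pair_gap=intra_pair_gap,
        inter_pair_range=inter_pair_range,
        level_db=level_db,
        tone_hz=tone_hz,
    )


def select_eligible_stimuli(
    train: StimulusTrain,
    hyp: Hypnogram,
    n_seconds: int,
    segment: tuple[float, float],
    stages: tuple[str, ...] = ("N2",),
    artifact_mask: np.ndarray | None = None,
) -> np.ndarray:
    """S1 onsets whose full analysis segment is artifact/arousal-free sleep
    of the requested stage(s).

    Eligibility is evaluated on the 1-s grid: every second overlapping
    [S1+segment[0], S1+segment[1]) must be eligible.
    """
    mask = hyp.eligible_seconds(n_seconds, stages=stages, artifact_mask=artifact_mask)
    out = []
    for s1 in train.s1_onsets:
        lo = s1 + segment[0]
        hi = s1 + segment[1]
        k0 = int(np.floor(lo))
        k1 = int(np.ceil(hi))
        if k0 < 0 or k1 > n_seconds:
            continue
        if mask[k0:k1].all():
            out.append(s1)
    return np.asarray(out, dtype=float)


def evoked_average(
    rec: Recording,
    s1_onsets: np.ndarray,
    channels: tuple[str, ...],
    window: tuple[float, float] = (-0.5, 2.0),
    baseline: tuple[float, float] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Stimulus-locked average across stimuli then channels.

    Baseline-corrected by the mean of the pre-S1 part of the window (or the
    explicit ``baseline`` interval).  Returns (times, erp).
    """
    if len(s1_onsets) == 0:
        raise InsufficientDataError("no eligible stimuli for the evoked average")
    fs = rec.fs
    i0 = int(round(window[0] * fs))
    i1 = int(round(window[1] * fs))
    times = np.arange(i0, i1) / fs
    if baseline is None:
        baseline = (window[0], 0.0)
    bsel = (times >= baseline[0]) & (times < baseline[1])
    epochs = []
    for ch in channels:
        x = rec.get(ch)
        for s1 in s1_onsets:
            c = int(round(s1 * fs))
            if c + i0 < 0 or c + i1 > rec.n_samples:
                continue
            epochs.append(x[c + i0 : c + i1])
    if not epochs:
        raise InsufficientDataError("no stimulus epoch lies fully inside the recording")
    erp = np.mean(epochs, axis=0)
    if bsel.any():
        erp = erp - erp[bsel].mean()
    return times, erp


def peak_latency_histogram(
    events: EventTable,
    train: StimulusTrain,
    bin_s: float = 0.05,
    span: tuple[float, float] = (-2.0, 4.0),
) -> dict[str, np.ndarray]:
    """Histogram of event negative-peak latencies relative to S1 and S2."""
    edges = np.arange(span[0], span[1] + bin_s / 2, bin_s)
    peaks = events.df["neg_peak_time"].dropna().to_numpy(float)
    out = {"bin_edges": edges}
    for key, onsets in (("s1", train.s1_onsets), ("s2", train.s2_onsets)):
        lat = []
        for t0 in onsets:
            sel = peaks[(peaks >= t0 + span[0]) & (peaks < t0 + span[1])]
            lat.extend(sel - t0)
        out[key] = np.histogram(lat, bins=edges)[0]
    return out


def event_likelihood(
    event_times: np.ndarray,
    eligible_s1: np.ndarray,
    window: tuple[float, float],
) -> float:
    """Events per eligible S1 whose time falls in the half-open window."""
    if len(eligible_s1) == 0:
        raise InsufficientDataError("no eligible stimuli (likelihood undefined)")
    event_times = np.asarray(event_times, dtype=float)
    count = 0
    for s1 in eligible_s1:
        count += int(
            np.sum((event_times >= s1 + window[0]) & (event_times < s1 + window[1]))
        )
    return count / len(eligible_s1)


def kcomplex_likelihood(
    sw_events: EventTable,
    eligible_s1: np.ndarray,
    windows: WindowSpec | None = None,
) -> tuple[float, float]:
    """(ON, OFF) K-complex likelihood from slow-wave negative peak times."""
    windows = windows or WindowSpec()
    windows.validate()
    peaks = sw_events.df["neg_peak_time"].dropna().to_numpy(float)
    return (
        event_likelihood(peaks, eligible_s1, windows.kc_on),
        event_likelihood(peaks, eligible_s1, windows.kc_off),
    )


def spindle_likelihood(
    spindle_events: EventTable,
    eligible_s1: np.ndarray,
    windows: WindowSpec | None = None,
) -> tuple[float, float]:
    """(ON, OFF) spindle likelihood; membership by event START time."""
    windows = windows or WindowSpec()
    windows.validate()
    onsets = spindle_events.df["onset"].to_numpy(float)
    return (
        event_likelihood(onsets, eligible_s1, windows.sp_on),
        event_likelihood(onsets, eligible_s1, windows.sp_off),
    )
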