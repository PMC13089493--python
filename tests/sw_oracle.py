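"""Independent brute-force slow-wave enumerator used as a test oracle.

Scans the band-passed signal sample by sample for zero crossings and applies
the five published criteria (negative/positive half-wave durations, negative
and positive peak amplitudes, peak-to-peak amplitude) by direct enumeration.
Deliberately written as a plain loop, independent of the package's
vectorized detector.
"""

import numpy as np

from napscape.slow_waves import SWParams


def brute_force_slow_waves(xf, fs, params: SWParams | None = None, eligible_mask=None):
    """Return a list of (onset_idx, zero_up_idx, end_idx, neg_peak_idx) tuples.

    Boundary convention shared with the detector: a sample is 'negative'
    when strictly below zero; half-waves run between consecutive crossings.
    """
    params = params or SWParams()
    n = len(xf)
    crossings = []
    for i in range(1, n):
        if (xf[i - 1] < 0) != (xf[i] < 0):
            crossings.append(i)
    accepted = []
    for k in range(len(crossings) - 2):
        i0, j, i1 = crossings[k], crossings[k + 1], crossings[k + 2]
        if not xf[i0] < 0:  # must start a negative half-wave
            continue
        neg_dur = (j - i0) / fs
        pos_dur = (i1 - j) / fs
        if not (params.neg_dur[0] <= neg_dur <= params.neg_dur[1]):
            continue
        if not (params.pos_dur[0] <= pos_dur <= params.pos_dur[1]):
            continue
        neg_peak = min(xf[i0:j])
        pos_peak = max(xf[j:i1])
        if not (-neg_peak > params.min_neg_amp):
            continue
        if not (pos_peak > params.min_pos_amp):
            continue
        if not (pos_peak - neg_peak > params.min_ptp):
            continue
        if eligible_mask is not None and not all(eligible_mask[i0:i1]):
            continue
        neg_peak_idx = i0 + int(np.argmin(xf[i0:j]))
        accepted.append((i0, j, i1, neg_peak_idx))
    return accepted
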