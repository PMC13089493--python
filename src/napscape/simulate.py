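"""Synthetic infant nap polysomnography.

The generator produces cohorts of naps with the statistical structure the
analysis pipeline assumes: 1/f NREM background EEG with stage-dependent
amplitude, embedded sleep spindles (sigma-band bursts with raised-cosine
tapered envelopes), biphasic slow waves satisfying the infant amplitude
criteria, K-complexes evoked 450-700 ms after tone onsets with a planted
probability, paired-tone stimulus trains, arousals, 1-s artifacts, and a
cohort layer (two counterbalanced nap conditions per subject, per-subject
sensory-reactivity scores, questionnaire items, and outcome rows drawn from
a planted linear mixed model so parameter recovery is well defined).

Defaults are calibrated to the study conditions: ~60/51-minute naps with
>= 95% sleep efficiency, ~5.4 arousals and ~3.6% artifact time per nap,
reactivity scores in the observed 1.14-2.78 range with a median of one
"not applicable" questionnaire response.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy import stats as sstats

from .errors import ParameterError
from .io import (
    EVENT_COLUMNS,
    ITEM_COLUMNS,
    N_ITEMS,
    Arousal,
    EventTable,
    Hypnogram,
    Recording,
    StimulusTrain,
    seconds_to_samples,
)
from .sensory import score_reactivity, QuestionnaireResponse
from .stimlock import generate_stimulus_train

SCALP_CHANNELS = ("F3", "Fz", "F4", "FC1", "FC2", "C3", "Cz", "C4", "O1", "Oz")
MASTOID_CHANNELS = ("TP9", "TP10")
DEFAULT_CHANNELS = SCALP_CHANNELS + MASTOID_CHANNELS

#: broadband background RMS (µV) per stage; N3 > N2 > N1/REM > W ordering only
STAGE_RMS = {"W": 25.0, "N1": 30.0, "N2": 40.0, "N3": 60.0, "REM": 30.0}


# ---------------------------------------------------------------------------
# Nap-level specification
# ---------------------------------------------------------------------------


@dataclass
class NapSpec:
    """Parameters for one synthetic nap."""

    fs: float = 500.0
    duration_min: float = 60.0  # total sleep time target
    sol_min: float = 10.0  # sleep onset latency (wake before sleep)
    condition: str = "baseline"  # baseline | stimulation
    channels: tuple[str, ...] = DEFAULT_CHANNELS
    one_over_f_exponent: float = 1.8
    low_freq_plateau: float = 0.3  # Hz below which the background spectrum is flat
    stage_rms: dict = field(default_factory=lambda: dict(STAGE_RMS))
    mastoid_rms_factor: float = 0.5
    # spindles
    spindle_rate_per_min: dict = field(default_factory=lambda: {"N2": 3.0, "N3": 0.5})
    #: sigma-band RMS of the burst at envelope peak over background sigma-band
    #: RMS, i.e. peak amplitude = sqrt(2) * snr * background sigma RMS
    spindle_snr: float = 3.0
    spindle_dur_range: tuple[float, float] = (0.5, 2.0)
    spindle_freq_range: tuple[float, float] = (10.0, 14.0)
    # slow waves
    sw_rate_per_min: dict = field(default_factory=lambda: {"N2": 3.0, "N3": 6.0})
    sw_neg_amp_range: tuple[float, float] = (60.0, 120.0)
    # evoked K-complexes (stimulation condition only)
    p_evoked: float = 0.35
    kc_neg_amp_range: tuple[float, float] = (150.0, 220.0)
    kc_latency_mean: float = 0.55
    kc_latency_sd: float = 0.04
    kc_latency_bounds: tuple[float, float] = (0.45, 0.70)
    stim_start_after_onset_s: float = 120.0
    # arousals / artifacts
    arousal_rate_per_nap: float = 5.4
    artifact_fraction: float = 0.036
    min_event_separation_s: float = 2.5


@dataclass
class SimulatedNap:
    recording: Recording
    hypnogram: Hypnogram
    events: EventTable  # ground truth, exact to the sample
    train: StimulusTrain | None


# ---------------------------------------------------------------------------
# Hypnogram simulation
# ---------------------------------------------------------------------------

_BOUT_MEAN_EPOCHS = {"N1": 6, "N2": 16, "N3": 20, "REM": 10}
_TRANSITIONS = {
    "N1": (("N2", 0.9), ("REM", 0.1)),
    "N2": (("N3", 0.55), ("N1", 0.15), ("REM", 0.3)),
    "N3": (("N2", 0.95), ("N1", 0.05)),
    "REM": (("N1", 0.5), ("N2", 0.5)),
}


def simulate_hypnogram(
    rng: np.random.Generator,
    duration_min: float = 60.0,
    sol_min: float = 10.0,
    wake_bout_prob: float = 0.04,
) -> Hypnogram:
    """Semi-Markov stage bouts after an initial wake period.

    Bout lengths are geometric around stage-typical means, scaled down for
    short naps so the stage mixture stays representative; rare brief wake
    bouts keep sleep efficiency above ~95%.
    """
    epochs: list[str] = ["W"] * max(int(round(sol_min * 2)), 1)
    n_sleep = int(round(duration_min * 2))
    bout_scale = float(np.clip(duration_min / 60.0, 0.15, 1.0))
    stage = "N1"
    placed = 0
    while placed < n_sleep:
        mean = max(_BOUT_MEAN_EPOCHS[stage] * bout_scale, 1.0)
        bout = min(1 + rng.geometric(1.0 / mean), n_sleep - placed)
        epochs.extend([stage] * bout)
        placed += bout
        if placed < n_sleep and rng.random() < wake_bout_prob:
            epochs.append("W")  # brief awakening (not counted as sleep)
        nxt, probs = zip(*_TRANSITIONS[stage])
        stage = nxt[rng.choice(len(nxt), p=np.array(probs) / sum(probs))]
    return Hypnogram(epochs, lights_off=0.0)


# ---------------------------------------------------------------------------
# Background and waveform synthesis
# ---------------------------------------------------------------------------


def _background(rng, n, fs, exponent, plateau):
    """Unit-RMS spectrally shaped (1/f^exponent power) Gaussian noise."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, d=1 / fs)
    shape = np.maximum(f, plateau) ** (-exponent / 2)
    shape[0] = 0.0
    x = np.fft.irfft(spec * shape, n)
    return x / x.std()


def sigma_rms_fraction(
    exponent: float, plateau: float, band=(9.0, 16.0), total=(0.2, 40.0), n=4096
) -> float:
    """Fraction of background RMS in the sigma band (from the spectral shape)."""
    f = np.linspace(total[0], total[1], n)
    p = np.maximum(f, plateau) ** (-exponent)
    tot = np.trapezoid(p, f)
    sel = (f >= band[0]) & (f <= band[1])
    return float(np.sqrt(np.trapezoid(p[sel], f[sel]) / tot))


def band_rms_fraction(
    exponent: float, plateau: float, band: tuple[float, float], total=(0.2, 40.0)
) -> float:
    return sigma_rms_fraction(exponent, plateau, band=band, total=total)


def spindle_waveform(rng, fs, dur_s, freq, amp) -> np.ndarray:
    """Sigma burst with a raised-cosine tapered (Tukey) envelope.

    Infant spindles lack the adult waxing-and-waning shape, so the envelope
    is mostly flat with short raised-cosine ramps (alpha = 0.2).
    """
    n = int(round(dur_s * fs))
    t = np.arange(n) / fs
    env = sps.windows.tukey(n, alpha=0.2)
    phase = rng.uniform(0, 2 * np.pi)
    return amp * env * np.sin(2 * np.pi * freq * t + phase)


def slow_wave_waveform(fs, neg_dur, pos_dur, neg_amp, pos_amp):
    """Biphasic slow wave: negative half-sine then positive half-sine.

    Returns (waveform, neg_peak_offset_s).  The half-wave durations and
    amplitudes are drawn to satisfy the detection criteria by construction.
    """
    n_neg = int(round(neg_dur * fs))
    n_pos = int(round(pos_dur * fs))
    w = np.concatenate(
        [
            -neg_amp * np.sin(np.pi * np.arange(n_neg) / n_neg),
            pos_amp * np.sin(np.pi * np.arange(n_pos) / n_pos),
        ]
    )
    return w, neg_dur / 2.0


# ---------------------------------------------------------------------------
# Nap simulation
# ---------------------------------------------------------------------------


def _stage_amplitude_envelope(hyp: Hypnogram, n_samples: int, fs: float, stage_rms):
    sec = hyp.stages_per_second(int(np.ceil(n_samples / fs)))
    amp_sec = np.array([stage_rms[s] for s in sec], dtype=float)
    # 3-s moving average avoids step discontinuities at stage boundaries
    kernel = np.ones(3) / 3
    amp_smooth = np.convolve(np.pad(amp_sec, 1, mode="edge"), kernel, mode="valid")
    t_sec = np.arange(len(amp_smooth)) + 0.5
    t = np.arange(n_samples) / fs
    return np.interp(t, t_sec, amp_smooth)


def _poisson_times(rng, eligible_sec_idx, rate_per_min, min_sep, existing):
    """Event start seconds at a per-minute rate on the eligible 1-s grid,
    respecting a minimum separation from already placed events."""
    out = []
    n = len(eligible_sec_idx)
    if n == 0:
        return out
    k = rng.poisson(rate_per_min * n / 60.0)
    candidates = rng.choice(eligible_sec_idx, size=min(k * 3 + 10, n), replace=False)
    taken = list(existing)
    for c in np.sort(candidates):
        t = float(c) + rng.uniform(0.0, 1.0)
        if all(abs(t - t0) >= min_sep for t0 in taken):
            out.append(t)
            taken.append(t)
        if len(out) >= k:
            break
    return out


def simulate_nap(spec: NapSpec, seed: int | np.random.Generator) -> SimulatedNap:
    """Simulate one nap: recording, hypnogram, ground-truth events, stimuli."""
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    if spec.condition not in ("baseline", "stimulation"):
        raise ParameterError(f"unknown condition {spec.condition!r}")
    fs = spec.fs
    hyp = simulate_hypnogram(rng, spec.duration_min, spec.sol_min)
    n_samples = int(hyp.duration_s * fs)
    n_seconds = int(hyp.duration_s)
    stage_sec = hyp.stages_per_second(n_seconds)

    # --- arousals -----------------------------------------------------------
    sleep_sec = np.flatnonzero(np.isin(stage_sec, ("N1", "N2", "N3", "REM")))
    arousals = []
    n_arousals = rng.poisson(spec.arousal_rate_per_nap * spec.duration_min / 60.0)
    for _ in range(n_arousals):
        onset = float(rng.choice(sleep_sec))
        dur = float(rng.uniform(3.0, 15.0))
        external = rng.random() < 0.1
        arousals.append(Arousal(onset, dur, external))
    hyp.arousals = sorted(arousals, key=lambda a: a.onset)

    # --- artifact seconds ---------------------------------------------------
    artifact_mask = np.zeros(n_seconds, dtype=bool)
    n_art = int(round(spec.artifact_fraction * n_seconds))
    if n_art:
        artifact_mask[rng.choice(n_seconds, size=n_art, replace=False)] = True
    hyp.artifact_mask = artifact_mask

    # --- stimulus train -----------------------------------------------------
    train = None
    if spec.condition == "stimulation":
        first_sleep = float(np.flatnonzero(np.isin(stage_sec, ("N1", "N2", "N3", "REM")))[0])
        start = first_sleep + spec.stim_start_after_onset_s
        span = hyp.duration_s - start - 5.0
        if span > 25:
            train = generate_stimulus_train(span, rng).shifted(start)

    # --- event planting -----------------------------------------------------
    arousal_sec = hyp.arousal_mask_seconds(n_seconds)
    plantable = {
        st: np.flatnonzero((stage_sec == st) & ~artifact_mask & ~arousal_sec)
        for st in ("N2", "N3")
    }
    events: list[dict] = []
    placed_sw: list[float] = []
    placed_sp: list[float] = []

    sig_frac = sigma_rms_fraction(spec.one_over_f_exponent, spec.low_freq_plateau)

    def add_wave(buffer, t0, wave):
        i0 = int(round(t0 * fs))
        i1 = i0 + len(wave)
        if 0 <= i0 and i1 <= n_samples:
            buffer[i0:i1] += wave
            return True
        return False

    wave_buffer = np.zeros(n_samples)

    # evoked K-complexes (neg peak at S1 + latency)
    if train is not None and spec.p_evoked > 0:
        lat_dist = sstats.truncnorm(
            (spec.kc_latency_bounds[0] - spec.kc_latency_mean) / spec.kc_latency_sd,
            (spec.kc_latency_bounds[1] - spec.kc_latency_mean) / spec.kc_latency_sd,
            loc=spec.kc_latency_mean,
            scale=spec.kc_latency_sd,
        )
        for s1 in train.s1_onsets:
            st = stage_sec[min(int(s1), n_seconds - 1)]
            if st not in ("N2", "N3"):
                continue
            if rng.random() >= spec.p_evoked:
                continue
            lat = float(lat_dist.rvs(random_state=rng))
            neg_dur = rng.uniform(0.5, 0.7)
            pos_dur = rng.uniform(0.3, 0.7)
            neg_amp = rng.uniform(*spec.kc_neg_amp_range)
            pos_amp = rng.uniform(40.0, 70.0)
            wave, peak_off = slow_wave_waveform(fs, neg_dur, pos_dur, neg_amp, pos_amp)
            t0 = s1 + lat - peak_off
            if add_wave(wave_buffer, t0, wave):
                placed_sw.append(t0 + peak_off)
                events.append(
                    {
                        "type": "slow_wave",
                        "channel": "Cz",
                        "onset": t0,
                        "offset": t0 + neg_dur + pos_dur,
                        "neg_peak_time": t0 + peak_off,
                        "neg_peak_amp": -neg_amp,
                        "pos_peak_amp": pos_amp,
                        "stage": st,
                    }
                )

    # spontaneous slow waves
    for st, rate in spec.sw_rate_per_min.items():
        for t0 in _poisson_times(rng, plantable.get(st, []), rate, spec.min_event_separation_s, placed_sw):
            neg_dur = rng.uniform(0.4, 1.0)
            pos_dur = rng.uniform(0.2, 0.8)
            neg_amp = rng.uniform(*spec.sw_neg_amp_range)
            pos_amp = rng.uniform(20.0, 50.0)
            wave, peak_off = slow_wave_waveform(fs, neg_dur, pos_dur, neg_amp, pos_amp)
            if add_wave(wave_buffer, t0, wave):
                placed_sw.append(t0 + peak_off)
                events.append(
                    {
                        "type": "slow_wave",
                        "channel": "Cz",
                        "onset": t0,
                        "offset": t0 + neg_dur + pos_dur,
                        "neg_peak_time": t0 + peak_off,
                        "neg_peak_amp": -neg_amp,
                        "pos_peak_amp": pos_amp,
                        "stage": st,
                    }
                )

    # sleep spindles
    spindle_buffer = np.zeros(n_samples)
    for st, rate in spec.spindle_rate_per_min.items():
        sigma_bg = spec.stage_rms[st] * sig_frac
        for t0 in _poisson_times(rng, plantable.get(st, []), rate, spec.min_event_separation_s, placed_sp):
            dur = rng.uniform(*spec.spindle_dur_range)
            freq = rng.uniform(*spec.spindle_freq_range)
            amp = np.sqrt(2.0) * spec.spindle_snr * sigma_bg
            wave = spindle_waveform(rng, fs, dur, freq, amp)
            if add_wave(spindle_buffer, t0, wave):
                placed_sp.append(t0)
                events.append(
                    {
                        "type": "spindle",
                        "channel": "Cz",
                        "onset": t0,
                        "offset": t0 + dur,
                        "neg_peak_time": t0 + dur / 2,
                        "neg_peak_amp": np.nan,
                        "pos_peak_amp": amp,
                        "stage": st,
                    }
                )

    # --- assemble channels --------------------------------------------------
    amp_env = _stage_amplitude_envelope(hyp, n_samples, fs, spec.stage_rms)
    art_burst = seconds_to_samples(artifact_mask, fs, n_samples)
    data = np.empty((len(spec.channels), n_samples))
    for i, ch in enumerate(spec.channels):
        bg = _background(rng, n_samples, fs, spec.one_over_f_exponent, spec.low_freq_plateau)
        if ch in MASTOID_CHANNELS:
            x = bg * amp_env * spec.mastoid_rms_factor
        else:
            x = bg * amp_env + wave_buffer + spindle_buffer
        x = np.where(art_burst, x * 6.0, x)  # 1-s high-amplitude artifacts
        data[i] = x

    rec = Recording(
        channels=list(spec.channels),
        fs=fs,
        data=data,
        reference="online_FCz",
        meta={"condition": spec.condition},
    )
    ev = EventTable(pd.DataFrame(events, columns=list(EVENT_COLUMNS)))
    return SimulatedNap(recording=rec, hypnogram=hyp, events=ev, train=train)


# ---------------------------------------------------------------------------
# Cohort layer
# ---------------------------------------------------------------------------


@dataclass
class EffectSpec:
    """Planted fixed effects for one outcome in the cohort linear model."""

    intercept: float
    beta_stim: float
    beta_react: float
    beta_inter: float
    beta_sex: float = 0.0
    beta_age: float = 0.0  # per day
    subject_sd: float = 1.0
    resid_sd: float = 1.0


#: planted effect structure, calibrated to the reported unstandardized
#: estimates (stimulation / reactivity / interaction) per outcome
DEFAULT_EFFECTS = {
    "spindle_density": EffectSpec(2.5, -0.193, 0.436, -1.279, subject_sd=0.4, resid_sd=0.4),
    "sw_density": EffectSpec(14.0, -0.473, -3.672, -4.335, subject_sd=2.0, resid_sd=2.0),
    "swa": EffectSpec(2500.0, 129.65, -381.79, -164.85, subject_sd=400.0, resid_sd=400.0),
    "sigma": EffectSpec(20.0, 0.873, 1.0, -3.839, subject_sd=4.0, resid_sd=4.0),
    "nap_min": EffectSpec(62.2, -12.2, -0.4, 7.1, subject_sd=12.0, resid_sd=12.0),
    "arousal_density": EffectSpec(0.09, 0.002, -0.003, -0.007, subject_sd=0.02, resid_sd=0.02),
}


@dataclass
class CohortSpec:
    n_subjects: int = 35
    seed: int = 0
    effects: dict = field(default_factory=lambda: dict(DEFAULT_EFFECTS))
    reactivity_range: tuple[float, float] = (1.14, 2.78)
    reactivity_mean: float = 1.7
    reactivity_sd: float = 0.35
    # calibrated so 24 rounded/clipped items give Cronbach's alpha near 0.85
    item_noise_sd: float = 0.5
    na_base_prob: float = 0.02
    na_hard_items: tuple[int, ...] = (4, 9, 15, 20, 23)  # age-inappropriate items
    na_hard_prob: float = 0.2
    el_fraction: float = 8 / 41
    female_fraction: float = 18 / 41
    held_fraction: float = 29 / 41
    nap_spec: NapSpec = field(default_factory=NapSpec)


@dataclass
class CohortBundle:
    subjects: pd.DataFrame
    questionnaire: pd.DataFrame
    feature_rows: pd.DataFrame  # planted-model ground truth, one row per nap
    spec: CohortSpec


def simulate_questionnaire(rng, spec: CohortSpec, latent: np.ndarray) -> pd.DataFrame:
    """Item responses from latent reactivity + item noise + NA pattern.

    Raw items are on the 1-5 scale with 1 = almost always (high reactivity),
    i.e. raw = 6 - reversed; the composite scoring reverses them back.
    """
    rows = []
    for i, lat in enumerate(latent):
        reversed_scores = np.clip(
            np.round(lat + rng.normal(0, spec.item_noise_sd, N_ITEMS)), 1, 5
        )
        raw = 6 - reversed_scores
        na_p = np.full(N_ITEMS, spec.na_base_prob)
        na_p[list(spec.na_hard_items)] = spec.na_hard_prob
        raw = np.where(rng.random(N_ITEMS) < na_p, np.nan, raw)
        if np.isnan(raw).all():
            raw[0] = np.clip(round(6 - lat), 1, 5)
        rows.append({"subject": f"S{i + 1:03d}", **dict(zip(ITEM_COLUMNS, raw))})
    return pd.DataFrame(rows)


def simulate_subjects(rng, spec: CohortSpec) -> tuple[pd.DataFrame, pd.DataFrame]:
    n = spec.n_subjects
    a, b = spec.reactivity_range
    lat = sstats.truncnorm(
        (a - spec.reactivity_mean) / spec.reactivity_sd,
        (b - spec.reactivity_mean) / spec.reactivity_sd,
        loc=spec.reactivity_mean,
        scale=spec.reactivity_sd,
    ).rvs(size=n, random_state=rng)
    questionnaire = simulate_questionnaire(rng, spec, lat)
    reactivity = []
    for _, row in questionnaire.iterrows():
        resp = QuestionnaireResponse(str(row["subject"]), row[ITEM_COLUMNS].to_numpy(float))
        score, _ = score_reactivity(resp)
        reactivity.append(score)
    subjects = pd.DataFrame(
        {
            "subject": questionnaire["subject"],
            "reactivity": reactivity,
            "latent_reactivity": lat,
            "sex": (rng.random(n) < spec.female_fraction).astype(int),
            "age_days": np.round(rng.normal(301, 33, n)).clip(240, 340),
            "autism_likelihood": (rng.random(n) < spec.el_fraction).astype(int),
            "sleep_arrangement": (rng.random(n) < spec.held_fraction).astype(int),
            "first_condition": np.where(np.arange(n) % 2 == 0, "baseline", "stimulation"),
        }
    )
    return subjects, questionnaire


def simulate_feature_rows(rng, subjects: pd.DataFrame, effects: dict) -> pd.DataFrame:
    """One row per nap: outcomes from the planted linear mixed model.

    y = b0 + b_stim*cond + b_react*react + b_inter*cond*react
        + b_sex*sex + b_age*(age - 300) + u_subject + eps
    """
    rows = []
    intercepts = {
        out: rng.normal(0, eff.subject_sd, len(subjects)) for out, eff in effects.items()
    }
    for i, subj in subjects.reset_index(drop=True).iterrows():
        for cond_name, cond in (("baseline", 0), ("stimulation", 1)):
            row = {
                "subject": subj["subject"],
                "condition": cond,
                "condition_name": cond_name,
                "reactivity": subj["reactivity"],
                "sex": subj["sex"],
                "age": subj["age_days"],
                "autism_likelihood": subj["autism_likelihood"],
                "sleep_arrangement": subj["sleep_arrangement"],
            }
            for out, eff in effects.items():
                mu = (
                    eff.intercept
                    + eff.beta_stim * cond
                    + eff.beta_react * subj["reactivity"]
                    + eff.beta_inter * cond * subj["reactivity"]
                    + eff.beta_sex * subj["sex"]
                    + eff.beta_age * (subj["age_days"] - 300.0)
                    + intercepts[out][i]
                )
                row[out] = mu + rng.normal(0, eff.resid_sd)
            rows.append(row)
    return pd.DataFrame(rows)


def simulate_cohort(spec: CohortSpec) -> CohortBundle:
    """Cohort bundle: subjects, questionnaire, planted-model outcome rows.

    Per-subject reactivity is drawn once and shared across both conditions;
    condition order is counterbalanced.  EEG naps are simulated separately
    (``simulate_nap``) because most statistical tests only need the planted
    feature rows.
    """
    rng = np.random.default_rng(spec.seed)
    subjects, questionnaire = simulate_subjects(rng, spec)
    features = simulate_feature_rows(rng, subjects, spec.effects)
    return CohortBundle(
        subjects=subjects, questionnaire=questionnaire, feature_rows=features, spec=spec
    )


def simulate_likelihood_rows(
    rng,
    subjects: pd.DataFrame,
    intercept: float = 0.3,
    beta_window: float = 0.38,
    beta_react: float = -0.557,
    beta_inter: float = 0.335,
    subject_sd: float = 0.15,
    resid_sd: float = 0.15,
) -> pd.DataFrame:
    """Nap x stimulus-window rows (OFF=0/ON=1) for the likelihood models."""
    rows = []
    u = rng.normal(0, subject_sd, len(subjects))
    for i, subj in subjects.reset_index(drop=True).iterrows():
        for win in (0, 1):
            mu = (
                intercept
                + beta_window * win
                + beta_react * subj["reactivity"]
                + beta_inter * win * subj["reactivity"]
                + u[i]
            )
            rows.append(
                {
                    "subject": subj["subject"],
                    "stim_window": win,
                    "reactivity": subj["reactivity"],
                    "sex": subj["sex"],
                    "age": subj["age_days"],
                    "autism_likelihood": subj["autism_likelihood"],
                    "likelihood": mu + rng.normal(0, resid_sd),
                }
            )
    return pd.DataFrame(rows)


def simulate_stage_proportions(
    rng,
    n_subjects: int = 40,
    stage_logits: dict | None = None,
    condition_effects: dict | None = None,
    reactivity_effects: dict | None = None,
    precision: float = 30.0,
    zero_prob: dict | None = None,
    subject_sd: float = 0.3,
) -> pd.DataFrame:
    """Long nap x stage table of beta-distributed stage proportions.

    Each stage proportion is drawn from a beta distribution whose logit mean
    carries the planted stage, condition and reactivity effects, with
    stage-specific zero inflation (REM = 0 naps exist by design).
    """
    stage_logits = stage_logits or {"N1": -1.5, "N2": -0.8, "N3": -0.6, "REM": -1.9}
    condition_effects = condition_effects or {}
    reactivity_effects = reactivity_effects or {}
    zero_prob = zero_prob or {"N1": 0.01, "N2": 0.0, "N3": 0.01, "REM": 0.12}
    rows = []
    for i in range(n_subjects):
        react = rng.uniform(1.14, 2.78)
        u = rng.normal(0, subject_sd)
        for cond in (0, 1):
            for stage, base in stage_logits.items():
                eta = (
                    base
                    + u
                    + condition_effects.get(stage, 0.0) * cond
                    + reactivity_effects.get(stage, 0.0) * cond * react
                )
                if rng.random() < zero_prob[stage]:
                    prop = 0.0
                else:
                    mu = 1.0 / (1.0 + np.exp(-eta))
                    prop = rng.beta(mu * precision, (1 - mu) * precision)
                rows.append(
                    {
                        "subject": f"S{i + 1:03d}",
                        "condition": cond,
                        "reactivity": react,
                        "stage": stage,
                        "prop": float(prop),
                    }
                )
    return pd.DataFrame(rows)
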