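"""Core data model and file I/O.

Recordings are stored as EDF (the PSG interchange format), hypnograms as
plain text (one 30-s epoch per line, metadata in ``#`` header lines), and
event tables / stimulus trains / questionnaires as CSV.  All event and
stimulus times are seconds from recording start, 0-based, with half-open
``[onset, offset)`` intervals.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import AlignmentError, FormatError, ValidationError

STAGES = ("W", "N1", "N2", "N3", "REM")
SLEEP_STAGES = ("N1", "N2", "N3", "REM")
EPOCH_S = 30.0

REFERENCES = ("online_FCz", "linked_mastoids", "contralateral_mastoids")

EVENT_TYPES = ("spindle", "slow_wave", "artifact", "arousal", "manual_spindle")
EVENT_COLUMNS = (
    "type",
    "channel",
    "onset",
    "offset",
    "neg_peak_time",
    "neg_peak_amp",
    "pos_peak_amp",
    "stage",
)


# ---------------------------------------------------------------------------
# Recording
# ---------------------------------------------------------------------------


@dataclass
class Recording:
    """Multichannel EEG in microvolts.

    ``data`` has shape ``(n_channels, n_samples)``.  ``reference`` tracks the
    referencing state (acquisition reference is FCz; analyses use linked
    mastoids).  ``bad_channels`` carries input metadata flags; they are not
    auto-detected.
    """

    channels: list[str]
    fs: float
    data: np.ndarray
    reference: str = "online_FCz"
    meta: dict = field(default_factory=dict)
    bad_channels: set = field(default_factory=set)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.fs <= 0:
            raise ValidationError(f"sampling rate must be positive, got {self.fs}")
        if self.data.ndim != 2:
            raise ValidationError("data must be 2-D (channels x samples)")
        if self.data.shape[0] != len(self.channels):
            raise ValidationError(
                f"{len(self.channels)} channel labels for {self.data.shape[0]} rows"
            )
        if self.data.shape[1] < 1:
            raise ValidationError("recording must contain at least one sample")
        if len(set(self.channels)) != len(self.channels):
            raise ValidationError("channel labels must be unique")
        if self.reference not in REFERENCES:
            raise ValidationError(f"unknown reference {self.reference!r}")

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def get(self, channel: str) -> np.ndarray:
        try:
            return self.data[self.channels.index(channel)]
        except ValueError:
            raise KeyError(f"channel {channel!r} not in recording") from None

    def copy_with(self, data: np.ndarray, reference: str | None = None) -> "Recording":
        return Recording(
            channels=list(self.channels),
            fs=self.fs,
            data=data,
            reference=reference or self.reference,
            meta=dict(self.meta),
            bad_channels=set(self.bad_channels),
        )


# ---------------------------------------------------------------------------
# Hypnogram
# ---------------------------------------------------------------------------


@dataclass
class Arousal:
    onset: float
    duration: float
    external: bool = False  # caused by a known external factor (experimenter note)

    def __post_init__(self):
        if self.duration < 3.0:
            raise ValidationError(
                f"arousals are >= 3 s by definition, got {self.duration}"
            )


@dataclass
class Hypnogram:
    """Sleep stages at 30-s resolution plus arousal and artifact annotations.

    ``artifact_mask`` is a boolean array at 1-s resolution (True = artifact).
    ``lights_off`` is carried as explicit metadata (seconds from recording
    start).
    """

    epoch_stages: list[str]
    arousals: list[Arousal] = field(default_factory=list)
    artifact_mask: np.ndarray | None = None
    lights_off: float = 0.0

    def __post_init__(self):
        bad = [s for s in self.epoch_stages if s not in STAGES]
        if bad:
            raise ValidationError(f"unknown stage codes: {sorted(set(bad))}")
        if self.artifact_mask is not None:
            self.artifact_mask = np.asarray(self.artifact_mask, dtype=bool)

    @property
    def n_epochs(self) -> int:
        return len(self.epoch_stages)

    @property
    def duration_s(self) -> float:
        return self.n_epochs * EPOCH_S

    def stages_per_second(self, n_seconds: int | None = None) -> np.ndarray:
        """Stage code for every 1-s bin (last epoch may be truncated)."""
        n_seconds = int(self.duration_s) if n_seconds is None else int(n_seconds)
        if n_seconds > self.duration_s + EPOCH_S:
            raise AlignmentError(
                f"hypnogram covers {self.duration_s} s, requested {n_seconds} s"
            )
        sec = np.repeat(np.asarray(self.epoch_stages, dtype=object), int(EPOCH_S))
        if n_seconds <= len(sec):
            return sec[:n_seconds]
        # within-one-epoch slack: pad with the final stage
        return np.concatenate([sec, np.repeat(sec[-1], n_seconds - len(sec))])

    def arousal_mask_seconds(self, n_seconds: int) -> np.ndarray:
        mask = np.zeros(n_seconds, dtype=bool)
        for a in self.arousals:
            lo = int(np.floor(a.onset))
            hi = int(np.ceil(a.onset + a.duration))
            mask[max(lo, 0) : min(hi, n_seconds)] = True
        return mask

    def eligible_seconds(
        self,
        n_seconds: int,
        stages: tuple[str, ...] = ("N2", "N3"),
        artifact_mask: np.ndarray | None = None,
        exclude_arousals: bool = True,
    ) -> np.ndarray:
        """1-s boolean mask of artifact/arousal-free time in the given stages."""
        stage_sec = self.stages_per_second(n_seconds)
        mask = np.isin(stage_sec, stages)
        art = artifact_mask if artifact_mask is not None else self.artifact_mask
        if art is not None:
            n = min(n_seconds, len(art))
            mask[:n] &= ~np.asarray(art[:n], dtype=bool)
        if exclude_arousals:
            mask &= ~self.arousal_mask_seconds(n_seconds)
        return mask


def seconds_to_samples(mask_s: np.ndarray, fs: float, n_samples: int) -> np.ndarray:
    """Expand a 1-s boolean mask to sample resolution."""
    out = np.repeat(np.asarray(mask_s, dtype=bool), int(round(fs)))
    if len(out) >= n_samples:
        return out[:n_samples]
    return np.concatenate([out, np.zeros(n_samples - len(out), dtype=bool)])


# ---------------------------------------------------------------------------
# Event tables
# ---------------------------------------------------------------------------


class EventTable:
    """Tabular detected/annotated events (spindles, slow waves, ...).

    Thin wrapper over a pandas DataFrame with fixed columns; validates the
    interval invariants on construction.
    """

    def __init__(self, df: pd.DataFrame | None = None):
        if df is None:
            df = pd.DataFrame({c: pd.Series(dtype=object) for c in EVENT_COLUMNS})
        df = df.copy().reset_index(drop=True)
        for c in EVENT_COLUMNS:
            if c not in df.columns:
                df[c] = np.nan
        df = df[list(EVENT_COLUMNS)]
        for c in ("onset", "offset", "neg_peak_time", "neg_peak_amp", "pos_peak_amp"):
            df[c] = pd.to_numeric(df[c], errors="coerce")
        self.df = df
        self._validate()

    def _validate(self):
        df = self.df
        if len(df) == 0:
            return
        bad_types = set(df["type"]) - set(EVENT_TYPES)
        if bad_types:
            raise ValidationError(f"unknown event types: {sorted(bad_types)}")
        if not (df["onset"] < df["offset"]).all():
            raise ValidationError("every event must satisfy onset < offset")
        pk = df["neg_peak_time"].to_numpy(float)
        has_pk = ~np.isnan(pk)
        if has_pk.any():
            on = df["onset"].to_numpy(float)[has_pk]
            off = df["offset"].to_numpy(float)[has_pk]
            if not ((pk[has_pk] >= on) & (pk[has_pk] <= off)).all():
                raise ValidationError("peak times must lie within [onset, offset]")

    @classmethod
    def from_records(cls, records: list[dict]) -> "EventTable":
        return cls(pd.DataFrame.from_records(records, columns=list(EVENT_COLUMNS)))

    def __len__(self) -> int:
        return len(self.df)

    def select(self, type: str | None = None, channel: str | None = None) -> "EventTable":
        df = self.df
        if type is not None:
            df = df[df["type"] == type]
        if channel is not None:
            df = df[df["channel"] == channel]
        return EventTable(df)

    def concat(self, other: "EventTable") -> "EventTable":
        return EventTable(pd.concat([self.df, other.df], ignore_index=True))


def write_events(table: EventTable, path: str | Path) -> None:
    table.df.to_csv(path, index=False)


def read_events(path: str | Path) -> EventTable:
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise FormatError(f"cannot read event CSV {path}: {exc}") from exc
    return EventTable(df)


# ---------------------------------------------------------------------------
# Stimulus trains
# ---------------------------------------------------------------------------


@dataclass
class StimulusTrain:
    """Paired-tone stimulation: ordered (S1, S2) onsets in seconds.

    Each pair is two ``tone_duration``-second tones separated by
    ``intra_pair_gap``; consecutive pairs are separated by a random gap in
    ``inter_pair_range``.
    """

    pairs: np.ndarray  # shape (n, 2)
    tone_duration: float = 1.0
    intra_pair_gap: float = 0.7
    inter_pair_range: tuple[float, float] = (12.0, 18.0)
    level_db: float = 60.0
    tone_hz: float = 225.0

    def __post_init__(self):
        self.pairs = np.asarray(self.pairs, dtype=float).reshape(-1, 2)
        if len(self.pairs):
            expected = self.pairs[:, 0] + self.tone_duration + self.intra_pair_gap
            if not np.allclose(self.pairs[:, 1], expected, atol=1e-6):
                raise ValidationError(
                    "S2 onset must equal S1 + tone_duration + intra_pair_gap"
                )
            d = np.diff(self.pairs[:, 0])
            min_sep = self.inter_pair_range[0] + self.pair_span
            if len(d) and d.min() < min_sep - 1e-6:
                raise ValidationError("stimulus pairs too closely spaced")

    @property
    def pair_span(self) -> float:
        """Time from S1 onset to the end of S2."""
        return 2 * self.tone_duration + self.intra_pair_gap

    @property
    def s1_onsets(self) -> np.ndarray:
        return self.pairs[:, 0]

    @property
    def s2_onsets(self) -> np.ndarray:
        return self.pairs[:, 1]

    def shifted(self, dt: float) -> "StimulusTrain":
        return StimulusTrain(
            self.pairs + dt,
            self.tone_duration,
            self.intra_pair_gap,
            self.inter_pair_range,
            self.level_db,
            self.tone_hz,
        )


def write_stimulus_train(train: StimulusTrain, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# tone_duration: {train.tone_duration!r}\n")
        fh.write(f"# intra_pair_gap: {train.intra_pair_gap!r}\n")
        fh.write(
            f"# inter_pair_range: {train.inter_pair_range[0]!r} {train.inter_pair_range[1]!r}\n"
        )
        fh.write(f"# level_db: {train.level_db!r}\n")
        fh.write(f"# tone_hz: {train.tone_hz!r}\n")
        fh.write("s1_onset,s2_onset\n")
        for s1, s2 in train.pairs:
            fh.write(f"{float(s1)!r},{float(s2)!r}\n")


def read_stimulus_train(path: str | Path) -> StimulusTrain:
    meta: dict = {}
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                key, _, val = line[1:].partition(":")
                meta[key.strip()] = val.split()
            elif line.startswith("s1_onset"):
                continue
            else:
                rows.append([float(x) for x in line.split(",")])
    try:
        return StimulusTrain(
            pairs=np.array(rows, dtype=float).reshape(-1, 2),
            tone_duration=float(meta["tone_duration"][0]),
            intra_pair_gap=float(meta["intra_pair_gap"][0]),
            inter_pair_range=(
                float(meta["inter_pair_range"][0]),
                float(meta["inter_pair_range"][1]),
            ),
            level_db=float(meta["level_db"][0]),
            tone_hz=float(meta["tone_hz"][0]),
        )
    except (KeyError, ValueError) as exc:
        raise FormatError(f"malformed stimulus train file {path}: {exc}") from exc


# ---------------------------------------------------------------------------
# Hypnogram text format
# ---------------------------------------------------------------------------


def write_hypnogram(hyp: Hypnogram, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("# napscape-hypnogram v1\n")
        fh.write(f"# lights_off: {hyp.lights_off!r}\n")
        for a in hyp.arousals:
            fh.write(f"# arousal: {a.onset!r} {a.duration!r} {int(a.external)}\n")
        if hyp.artifact_mask is not None:
            idx = np.flatnonzero(hyp.artifact_mask)
            fh.write(f"# artifact_n_seconds: {len(hyp.artifact_mask)}\n")
            fh.write("# artifact_seconds: " + " ".join(map(str, idx)) + "\n")
        for stage in hyp.epoch_stages:
            fh.write(stage + "\n")


def read_hypnogram(path: str | Path) -> Hypnogram:
    stages: list[str] = []
    arousals: list[Arousal] = []
    lights_off = 0.0
    art_idx: list[int] | None = None
    art_n: int | None = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                key, _, val = line[1:].partition(":")
                key = key.strip()
                if key == "lights_off":
                    lights_off = float(val)
                elif key == "arousal":
                    onset, dur, ext = val.split()
                    arousals.append(Arousal(float(onset), float(dur), bool(int(ext))))
                elif key == "artifact_n_seconds":
                    art_n = int(val)
                elif key == "artifact_seconds":
                    art_idx = [int(x) for x in val.split()]
                continue
            if line not in STAGES:
                raise FormatError(
                    f"{path}: unknown stage code {line!r} at line {lineno}"
                )
            stages.append(line)
    mask = None
    if art_n is not None:
        mask = np.zeros(art_n, dtype=bool)
        if art_idx:
            mask[np.asarray(art_idx, dtype=int)] = True
    return Hypnogram(stages, arousals, mask, lights_off)


# ---------------------------------------------------------------------------
# EDF read/write
# ---------------------------------------------------------------------------

_EDF_DIG_MAX = 32767


def _edf_field(value, width: int) -> bytes:
    s = str(value)
    if len(s) > width:
        raise ValueError(f"EDF header field {s!r} exceeds {width} chars")
    return s.ljust(width).encode("ascii")


def _edf_float(value: float, width: int = 8) -> bytes:
    for fmt in ("%g", "%.6g", "%.5g", "%.4g", "%.3g"):
        s = fmt % value
        if len(s) <= width:
            return s.ljust(width).encode("ascii")
    raise ValueError(f"cannot format {value} in {width} chars")


def write_recording(rec: Recording, path: str | Path) -> None:
    """Write a recording to EDF (16-bit, µV physical units).

    Uses 1-s data records when the length divides evenly, otherwise a single
    record spanning the recording.
    """
    n_ch, n_samp = rec.data.shape
    fs = rec.fs
    if abs(fs - round(fs)) < 1e-9 and n_samp % int(round(fs)) == 0:
        record_dur = 1.0
        spr = int(round(fs))
        n_rec = n_samp // spr
    else:
        record_dur = n_samp / fs
        spr = n_samp
        n_rec = 1

    header = bytearray()
    header += _edf_field("0", 8)
    header += _edf_field(rec.meta.get("subject", "X"), 80)
    header += _edf_field(rec.meta.get("condition", ""), 80)
    header += _edf_field("01.01.00", 8)
    header += _edf_field("00.00.00", 8)
    header += _edf_field(256 * (1 + n_ch), 8)
    header += _edf_field("", 44)
    header += _edf_field(n_rec, 8)
    header += _edf_float(record_dur, 8)
    header += _edf_field(n_ch, 4)

    phys_max = np.maximum(np.abs(rec.data).max(axis=1), 1e-6)
    # round-trip through the printed header value so scaling is exact on read
    pm_strings = [_edf_float(pm * 1.0001).decode().strip() for pm in phys_max]
    pm_values = np.array([float(s) for s in pm_strings])

    def block(values, width):
        return b"".join(_edf_field(v, width) for v in values)

    header += block(rec.channels, 16)
    header += block([""] * n_ch, 80)
    header += block(["uV"] * n_ch, 8)
    header += block(["-" + s for s in pm_strings], 8)
    header += block(pm_strings, 8)
    header += block([-_EDF_DIG_MAX] * n_ch, 8)
    header += block([_EDF_DIG_MAX] * n_ch, 8)
    header += block([""] * n_ch, 80)
    header += block([spr] * n_ch, 8)
    header += block([""] * n_ch, 32)

    scale = pm_values / _EDF_DIG_MAX  # µV per digital unit
    digital = np.round(rec.data / scale[:, None]).astype("<i2")

    with open(path, "wb") as fh:
        fh.write(bytes(header))
        for r in range(n_rec):
            seg = digital[:, r * spr : (r + 1) * spr]
            fh.write(seg.tobytes())


def _peek_edf_labels(path: str | Path) -> list[str]:
    with open(path, "rb") as fh:
        head = fh.read(256)
        if len(head) < 256:
            raise FormatError(f"{path}: truncated EDF header")
        try:
            n_ch = int(head[252:256].decode("ascii").strip())
        except ValueError as exc:
            raise FormatError(f"{path}: invalid EDF header") from exc
        if n_ch <= 0:
            raise FormatError(f"{path}: EDF file declares no signals")
        labels_raw = fh.read(16 * n_ch)
    return [
        labels_raw[i * 16 : (i + 1) * 16].decode("ascii", "replace").strip()
        for i in range(n_ch)
    ]


def read_recording(path: str | Path, meta: dict | None = None) -> Recording:
    """Read an EDF/EDF+ file into a µV-scaled Recording (via MNE)."""
    import mne

    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    labels = _peek_edf_labels(path)
    if len(set(labels)) != len(labels):
        raise ValidationError(f"{path}: duplicate channel labels in EDF header")
    try:
        raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    except Exception as exc:
        raise FormatError(f"cannot read EDF {path}: {exc}") from exc
    data_uv = raw.get_data() * 1e6
    return Recording(
        channels=list(raw.ch_names),
        fs=float(raw.info["sfreq"]),
        data=data_uv,
        reference=(meta or {}).get("reference", "online_FCz"),
        meta=meta or {},
    )


# ---------------------------------------------------------------------------
# Questionnaires
# ---------------------------------------------------------------------------

N_ITEMS = 24
ITEM_COLUMNS = [f"I{i:02d}" for i in range(1, N_ITEMS + 1)]


def write_questionnaire(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False, na_rep="NA")


def read_questionnaire(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, na_values=["NA"])
    missing = [c for c in ["subject", *ITEM_COLUMNS] if c not in df.columns]
    if missing:
        raise FormatError(f"questionnaire CSV missing columns: {missing}")
    vals = df[ITEM_COLUMNS].to_numpy(float)
    ok = np.isnan(vals) | ((vals >= 1) & (vals <= 5))
    if not ok.all():
        raise ValidationError("questionnaire items must be 1-5 or NA")
    return df
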