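"""Session containers and on-disk formats.

A recorded session lives in a directory: one raw little-endian float32
binary per channel (``chan00.f32`` ...; unit volts) plus a ``session.json``
sidecar with the sampling metadata.  Behavioral events, detected spikes and
feature tables are plain CSV (header row, ``.`` decimal, UTF-8).  Readers
validate invariants before returning; writers are deterministic.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "FormatError",
    "RecordingSession",
    "BehavioralLog",
    "read_session",
    "write_session",
    "read_events",
    "write_events",
    "read_spikes",
    "write_spikes",
    "write_features",
    "read_features",
    "read_config",
    "write_config",
]

CHANNEL_CATEGORIES = ("paw", "paw+neck", "neck", "none")
EVENT_TYPES = ("protract", "hit", "retract")

_SIDECAR = "session.json"
_DTYPE = "<f4"


class FormatError(ValueError):
    """A file or container violates the session/event format contract."""


@dataclass
class RecordingSession:
    """Multi-channel continuous recording plus per-channel annotations.

    signals are stored as float32 volts, channels x samples; the band field
    records the acquisition band-pass edges in Hz.  ``manual_thresholds``
    holds the once-per-session visually-set detection thresholds (volts,
    NaN where unset); they are required only for manual-threshold analysis.
    """

    fs: float
    signals: np.ndarray
    channel_categories: list[str]
    manual_thresholds: np.ndarray | None = None
    band: tuple[float, float] = (800.0, 8000.0)

    def __post_init__(self):
        self.signals = np.ascontiguousarray(self.signals, dtype=np.float32)
        if self.signals.ndim != 2:
            raise FormatError("signals must be a 2-D (channels x samples) array")
        if self.fs <= 0:
            raise FormatError("fs must be positive")
        if len(self.channel_categories) != self.n_channels:
            raise FormatError(
                f"{len(self.channel_categories)} categories for "
                f"{self.n_channels} channels"
            )
        for c in self.channel_categories:
            if c not in CHANNEL_CATEGORIES:
                raise FormatError(f"unknown channel category {c!r}")
        if self.manual_thresholds is not None:
            self.manual_thresholds = np.asarray(self.manual_thresholds,
                                                dtype=np.float64)
            if self.manual_thresholds.shape != (self.n_channels,):
                raise FormatError("one manual threshold per channel required")

    @property
    def n_channels(self) -> int:
        return self.signals.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signals.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def paw_channels(self) -> np.ndarray:
        """Indices of channels whose microstimulation response was a pure
        paw movement (the only channels used for decoding)."""
        return np.flatnonzero(np.asarray(self.channel_categories) == "paw")


@dataclass
class BehavioralLog:
    """Ordered paddle events: protract / hit / retract with trial grouping.

    ``events`` columns: time_s (float, strictly increasing), event_type,
    trial_id (int), accepted_flag (bool), failure_reason (str, "" if none).
    """

    events: pd.DataFrame = field(repr=False)

    def __post_init__(self):
        ev = self.events
        required = ["time_s", "event_type", "trial_id", "accepted_flag",
                    "failure_reason"]
        missing = [c for c in required if c not in ev.columns]
        if missing:
            raise FormatError(f"event log missing columns {missing}")
        ev = ev[required].copy()
        ev["time_s"] = ev["time_s"].astype(float)
        ev["trial_id"] = ev["trial_id"].astype(int)
        ev["accepted_flag"] = ev["accepted_flag"].astype(bool)
        ev["failure_reason"] = ev["failure_reason"].fillna("").astype(str)
        if not ev["event_type"].isin(EVENT_TYPES).all():
            bad = sorted(set(ev["event_type"]) - set(EVENT_TYPES))
            raise FormatError(f"unknown event_type values {bad}")
        t = ev["time_s"].to_numpy()
        if np.any(np.diff(t) <= 0):
            raise FormatError("event times must be strictly increasing")
        self.events = ev.reset_index(drop=True)

    def hits(self) -> pd.DataFrame:
        return self.events[self.events["event_type"] == "hit"]

    def trial_ids(self) -> np.ndarray:
        return np.unique(self.events["trial_id"].to_numpy())

    def retracted_epochs(self, t_end: float) -> list[tuple[float, float]]:
        """Paddle-retracted (inter-trial) spans, including the pre-session
        lead-in before the first protraction."""
        spans, open_t = [], 0.0
        for _, row in self.events.iterrows():
            if row.event_type == "protract" and open_t is not None:
                spans.append((open_t, row.time_s))
                open_t = None
            elif row.event_type == "retract":
                open_t = row.time_s
        if open_t is not None and open_t < t_end:
            spans.append((open_t, t_end))
        return spans


# ----------------------------------------------------------------- session

def write_session(session: RecordingSession, path) -> None:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    sidecar = {
        "fs": session.fs,
        "n_channels": session.n_channels,
        "samples_per_channel": session.n_samples,
        "channel_categories": list(session.channel_categories),
        "manual_thresholds": (
            None if session.manual_thresholds is None
            else [float(v) for v in session.manual_thresholds]
        ),
        "band_hz": list(session.band),
        "units": "volts",
        "dtype": _DTYPE,
    }
    (path / _SIDECAR).write_text(json.dumps(sidecar, indent=2) + "\n")
    for ch in range(session.n_channels):
        session.signals[ch].astype(_DTYPE).tofile(path / f"chan{ch:02d}.f32")


def read_session(path) -> RecordingSession:
    path = Path(path)
    sidecar_path = path / _SIDECAR
    if not sidecar_path.exists():
        raise FormatError(f"missing sidecar {sidecar_path}")
    meta = json.loads(sidecar_path.read_text())
    for key in ("fs", "n_channels", "samples_per_channel",
                "channel_categories"):
        if key not in meta:
            raise FormatError(f"sidecar missing field {key!r}")
    n_ch, n_s = int(meta["n_channels"]), int(meta["samples_per_channel"])
    signals = np.empty((n_ch, n_s), dtype=np.float32)
    for ch in range(n_ch):
        fname = path / f"chan{ch:02d}.f32"
        if not fname.exists():
            raise FormatError(f"missing channel file {fname.name}")
        raw = np.fromfile(fname, dtype=_DTYPE)
        if len(raw) != n_s:
            raise FormatError(
                f"channel {ch}: {len(raw)} samples on disk, sidecar says {n_s}"
            )
        signals[ch] = raw
    thr = meta.get("manual_thresholds")
    return RecordingSession(
        fs=float(meta["fs"]),
        signals=signals,
        channel_categories=list(meta["channel_categories"]),
        manual_thresholds=None if thr is None else np.asarray(thr, float),
        band=tuple(meta.get("band_hz", (800.0, 8000.0))),
    )


# ------------------------------------------------------------------ events

def write_events(log: BehavioralLog, path) -> None:
    log.events.to_csv(path, index=False)


def read_events(path) -> BehavioralLog:
    try:
        ev = pd.read_csv(path, keep_default_na=False,
                         na_values=[], dtype={"failure_reason": str})
    except (OSError, pd.errors.ParserError) as exc:
        raise FormatError(f"cannot parse event CSV {path}: {exc}") from exc
    return BehavioralLog(events=ev)


# ------------------------------------------------------------------ spikes

def write_spikes(trains, path) -> None:
    """Write detected spikes as CSV (channel, spike_time_s,
    threshold_at_event).  ``trains`` is an iterable of SpikeTrain."""
    rows = []
    for tr in trains:
        thr = tr.threshold_at(tr.spike_times)
        for t, th in zip(tr.spike_times, thr):
            rows.append((tr.channel, t, th))
    df = pd.DataFrame(rows, columns=["channel", "spike_time_s",
                                     "threshold_at_event"])
    df.to_csv(path, index=False)


def read_spikes(path) -> dict[int, np.ndarray]:
    """Read a spike CSV back as {channel: sorted spike times}."""
    df = pd.read_csv(path)
    out = {}
    for ch, grp in df.groupby("channel"):
        t = np.sort(grp["spike_time_s"].to_numpy(float))
        out[int(ch)] = t
    return out


# ---------------------------------------------------------------- features

def write_features(dataset, path) -> None:
    """Feature table CSV: one row per (trial, label, channel) with the three
    interval counts."""
    rows = []
    for trial_id, label, counts, channels in dataset.iter_rows():
        for ch, c3 in zip(channels, counts):
            rows.append((trial_id, label, ch, *[int(v) for v in c3]))
    df = pd.DataFrame(rows, columns=["trial_id", "label", "channel",
                                     "int1", "int2", "int3"])
    df.to_csv(path, index=False)


def read_features(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if not set(df["label"]) <= {"hit", "nohit"}:
        raise FormatError("feature labels must be 'hit' or 'nohit'")
    return df


# ------------------------------------------------------------------ config

def write_config(config, path) -> None:
    """Serialize a run configuration dataclass (SessionConfig,
    DenoiseConfig, DetectConfig or WindowSpec) to JSON with a type tag."""
    import dataclasses
    if not dataclasses.is_dataclass(config):
        raise FormatError("config must be a dataclass instance")
    doc = {"type": type(config).__name__,
           "fields": dataclasses.asdict(config)}
    Path(path).write_text(json.dumps(doc, indent=2, default=list) + "\n")


def read_config(path):
    """Inverse of :func:`write_config`."""
    # local imports: synth/denoise/detect/features themselves import io
    from .denoise import DenoiseConfig
    from .detect import DetectConfig
    from .features import WindowSpec
    from .synth import SessionConfig
    registry = {c.__name__: c for c in (SessionConfig, DenoiseConfig,
                                        DetectConfig, WindowSpec)}
    doc = json.loads(Path(path).read_text())
    if doc.get("type") not in registry:
        raise FormatError(f"unknown config type {doc.get('type')!r}")
    cls = registry[doc["type"]]
    fields = {k: tuple(v) if isinstance(v, list) else v
              for k, v in doc["fields"].items()}
    return cls(**fields)
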