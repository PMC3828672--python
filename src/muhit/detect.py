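"""Multi-unit spike detection by adaptive or manual thresholding.

The detector marks a spike wherever the signal makes an excursion beyond a
threshold.  In adaptive mode the threshold is recomputed on consecutive
non-overlapping windows (400 ms by default) as

    Thr_D = 4 * sigma_D,      sigma_D = median(|x|) / 0.6745,

the median-based robust scale that stays put when spikes are frequent or
large (unlike an RMS estimate, which a high firing rate inflates).  In
manual mode a single threshold -- the once-per-session, visually chosen
level of routine practice -- is applied throughout.  A spike's timestamp is
the extremum within 1 ms of the first threshold crossing, and a refractory
period (1 ms default) suppresses later crossings, keeping the earlier one.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DetectConfig",
    "SpikeTrain",
    "sigma_d",
    "adaptive_threshold",
    "detect_spikes",
    "count_in_interval",
]


@dataclass(frozen=True)
class DetectConfig:
    """Detector settings; ``manual_threshold`` (volts) is required only in
    manual mode.  Polarity 'absolute' triggers on |x|, 'negative' on
    x < -thr, 'positive' on x > thr."""

    mode: str = "adaptive"
    window_s: float = 0.400
    refractory_s: float = 0.001
    polarity: str = "absolute"
    manual_threshold: float | None = None

    def __post_init__(self):
        if self.mode not in ("adaptive", "manual"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.polarity not in ("absolute", "negative", "positive"):
            raise ValueError(f"unknown polarity {self.polarity!r}")
        if self.window_s <= 0:
            raise ValueError("window_s must be positive")
        if self.refractory_s < 0:
            raise ValueError("refractory_s must be >= 0")
        if self.mode == "manual" and self.manual_threshold is None:
            raise ValueError("manual mode requires manual_threshold")


@dataclass
class SpikeTrain:
    """Detected (or ground-truth) spikes of one channel.

    ``window_thresholds`` is the per-window threshold trace actually applied
    (length = number of detection windows; a single value in manual mode).
    """

    channel: int
    spike_times: np.ndarray
    window_thresholds: np.ndarray = field(default_factory=lambda: np.empty(0))
    window_s: float = 0.400

    def __post_init__(self):
        self.spike_times = np.asarray(self.spike_times, dtype=np.float64)
        self.window_thresholds = np.asarray(self.window_thresholds,
                                            dtype=np.float64)
        if np.any(np.diff(self.spike_times) <= 0):
            raise ValueError("spike times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.spike_times)

    def threshold_at(self, times) -> np.ndarray:
        """Threshold in force at each time (for spike-table export)."""
        times = np.atleast_1d(np.asarray(times, dtype=np.float64))
        if self.window_thresholds.size == 0:
            return np.full(times.shape, np.nan)
        idx = np.minimum((times / self.window_s).astype(int),
                         len(self.window_thresholds) - 1)
        return self.window_thresholds[idx]


def sigma_d(window: np.ndarray) -> float:
    """Robust noise scale: median(|x|) / 0.6745."""
    x = np.asarray(window)
    if x.size == 0:
        raise ValueError("empty window")
    return float(np.median(np.abs(x)) / 0.6745)


def adaptive_threshold(window: np.ndarray) -> float:
    """Detection threshold Thr_D = 4 * sigma_D of the window."""
    return 4.0 * sigma_d(window)


def _excursion(x: np.ndarray, thr: np.ndarray, polarity: str) -> np.ndarray:
    if polarity == "absolute":
        return np.abs(x) > thr
    if polarity == "negative":
        return x < -thr
    return x > thr


def detect_spikes(signal: np.ndarray, fs: float,
                  config: DetectConfig = DetectConfig(),
                  channel: int = 0) -> SpikeTrain:
    """Detect spikes on one channel.

    The signal must hold at least one detection window.  In adaptive mode
    the threshold is recomputed per consecutive non-overlapping window; a
    trailing partial window uses its own samples.
    """
    x = np.asarray(signal, dtype=np.float64)
    n = len(x)
    win = int(round(config.window_s * fs))
    if n < win:
        raise ValueError(
            f"signal ({n} samples) shorter than one {config.window_s * 1e3:g}"
            " ms detection window"
        )
    n_win = int(np.ceil(n / win))
    if config.mode == "manual":
        thr_win = np.full(n_win, float(config.manual_threshold))
    else:
        thr_win = np.array([
            adaptive_threshold(x[i * win:(i + 1) * win]) for i in range(n_win)
        ])
    thr = np.repeat(thr_win, win)[:n]

    exceed = _excursion(x, thr, config.polarity)
    onsets = np.flatnonzero(exceed & ~np.concatenate(([False], exceed[:-1])))

    # timestamp = extremum of the triggering deflection within 1 ms of the
    # first crossing
    search = max(int(round(0.001 * fs)), 1)
    times = np.empty(len(onsets))
    for k, i in enumerate(onsets):
        seg = x[i:i + search]
        if config.polarity == "negative":
            j = int(np.argmin(seg))
        elif config.polarity == "positive":
            j = int(np.argmax(seg))
        else:
            j = int(np.argmax(np.abs(seg)))
        times[k] = (i + j) / fs

    # refractory pass in first-crossing order: keep the earlier spike
    if config.refractory_s > 0 and len(times):
        kept = [times[0]]
        for t in times[1:]:
            if t - kept[-1] >= config.refractory_s:
                kept.append(t)
        times = np.array(kept)

    # extremum search may reorder/duplicate timestamps of adjacent onsets
    times = np.unique(times)
    return SpikeTrain(channel=channel, spike_times=times,
                      window_thresholds=thr_win, window_s=config.window_s)


def count_in_interval(train: SpikeTrain, t0: float, t1: float) -> int:
    """Number of spikes in the half-open interval [t0, t1)."""
    if t0 > t1:
        raise ValueError("t0 must be <= t1")
    t = train.spike_times
    return int(np.searchsorted(t, t1, "left") - np.searchsorted(t, t0, "left"))
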