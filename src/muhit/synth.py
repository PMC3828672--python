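"""Synthetic multi-unit M1 sessions with paddle-hit behavior.

The generator emulates the statistical structure the decoding pipeline
assumes, so every stage can be validated against a known ground truth:

* a behavioral protocol of self-paced trials -- three consecutive paddle
  hits per trial, 9 s paddle retraction after each trial, occasional
  failure trials (non-preferred limb, premature hit) and occasional hit
  pairs closer than 200 ms, both of which the analysis must discard;
* per-channel multi-unit spike trains: 2-5 units per electrode, each an
  inhomogeneous Poisson process whose rate rises by a configurable factor
  in a window preceding every hit (default onset 300 ms before contact,
  matching the forelimb EMG lead time in rats), merged and subjected to a
  1 ms refractory;
* biphasic, negative-leading ~1 ms spike waveforms, band-limited to the
  0.8-8 kHz acquisition band, with per-unit and per-spike amplitude
  scatter;
* additive noise (white, white+pink, or white plus artifact bursts) whose
  amplitude is raised by a configurable broadband gain while the paddle is
  retracted -- the epochs that furnish "no-hit" windows -- mirroring the
  higher background activity seen between hitting sequences.

Everything is reproducible: one integer seed determines the session
bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np


from .io import BehavioralLog, RecordingSession
import pandas as pd

__all__ = [
    "SessionConfig",
    "GroundTruth",
    "make_template",
    "generate_spike_train",
    "render_signal",
    "add_noise",
    "generate_behavior",
    "generate_session",
]

_MOVEMENT_CATEGORIES = ("paw", "paw+neck")   # rate-modulated channels
_RATE_FS = 1000.0                            # Hz, rate-profile sampling


@dataclass(frozen=True)
class SessionConfig:
    """Stated world of one synthetic session.

    Amplitude and noise defaults put the nominal unit peak at 8x the noise
    standard deviation (comfortable detection); :meth:`low_snr` drops it to
    5x.  ``hit_modulation`` is the multiplicative firing-rate gain on
    movement channels in the pre-hit window; it is a free parameter of the
    simulated world (the recordings it emulates quantify only that
    classification succeeds, not the underlying rate change).
    """

    n_trials: int = 10
    fs: float = 24414.0
    n_channels: int = 4
    channel_categories: tuple = ("paw", "paw", "neck", "none")
    baseline_rate_hz: float = 20.0
    hit_modulation: float = 3.0
    premovement_onset_ms: float = -300.0
    spike_amplitude_v: float = 80e-6
    amplitude_jitter: float = 0.1
    units_per_channel: tuple = (2, 5)
    noise_sigma_v: float = 10e-6
    noise_model: str = "white"
    nohit_background_gain: float = 1.5
    background_elevated_prob: float = 0.7
    refractory_s: float = 0.001
    manual_threshold_bias: float = 0.20
    failure_fraction: float = 0.1
    short_pair_fraction: float = 0.05
    hit_latency_range_s: tuple = (0.9, 1.6)
    inter_hit_range_s: tuple = (0.4, 1.2)
    retract_delay_s: float = 0.1
    retraction_s: float = 9.0
    lead_in_s: float = 1.0
    duration_s: float | None = None
    seed: int = 0

    def __post_init__(self):
        if self.baseline_rate_hz <= 0:
            raise ValueError("baseline_rate_hz must be positive")
        if self.fs <= 2 * 8000.0:
            raise ValueError("fs must exceed twice the 8 kHz band edge")
        if self.n_trials < 1:
            raise ValueError("need at least one trial")
        if self.hit_modulation < 0 or self.nohit_background_gain < 0:
            raise ValueError("gains must be non-negative")

    def categories(self) -> list[str]:
        """Channel categories cycled/truncated to n_channels."""
        reps = -(-self.n_channels // len(self.channel_categories))
        return list(self.channel_categories * reps)[: self.n_channels]

    @classmethod
    def low_snr(cls, seed: int = 0, n_trials: int = 12) -> "SessionConfig":
        """Single-paw-channel session with 5-sigma units: the noisy regime
        where denoising before detection should pay off."""
        return cls(n_trials=n_trials, n_channels=1,
                   channel_categories=("paw",), spike_amplitude_v=50e-6,
                   noise_sigma_v=10e-6, seed=seed)

    @classmethod
    def null(cls, seed: int = 0, n_trials: int = 8) -> "SessionConfig":
        """No rate modulation, equal backgrounds, clean protocol: the
        labels carry no information, so downstream decoding must sit at
        chance."""
        return cls(n_trials=n_trials, n_channels=1,
                   channel_categories=("paw",), hit_modulation=1.0,
                   nohit_background_gain=1.0, failure_fraction=0.0,
                   short_pair_fraction=0.0, seed=seed)


@dataclass
class GroundTruth:
    """Everything the generator knew: per-channel merged spike times
    (sorted, gaps >= the simulator refractory), the rate profiles they were
    drawn from, the nominal waveform, and the true noise scale."""

    spike_times: list
    rate_fs: float
    rate_profiles: np.ndarray         # (n_channels, n_rate_samples), Hz
    template: np.ndarray              # nominal waveform, volts
    template_peak_v: float
    polarity: str
    noise_sigma_true: float
    burst_intervals: list = field(default_factory=list)

    def expected_count(self, channel: int, t0: float, t1: float) -> float:
        """Integral of the channel's rate over [t0, t1) (spikes)."""
        r = self.rate_profiles[channel]
        i0, i1 = int(round(t0 * self.rate_fs)), int(round(t1 * self.rate_fs))
        return float(np.sum(r[i0:i1]) / self.rate_fs)


def make_template(fs: float = 24414.0,
                  amplitude_v: float = 80e-6) -> np.ndarray:
    """Biphasic, negative-leading action-potential waveform (~1 ms).

    A 0.4 ms negative lobe followed by a 0.6 ms positive overshoot whose
    area cancels the negative lobe's: the waveform is exactly zero-mean,
    so its spectral content concentrates around 1-2 kHz inside the
    acquisition band with no DC leakage (an explicit causal band-pass at
    the 0.8 kHz edge would distort the lobe balance more than it removes
    out-of-band energy).  Peak absolute amplitude equals ``amplitude_v``
    and falls in the negative lobe.
    """
    n_neg = max(int(round(0.4e-3 * fs)), 2)
    n_pos = (3 * n_neg) // 2
    neg = -np.sin(np.pi * (np.arange(n_neg) + 0.5) / n_neg)
    pos = np.sin(np.pi * (np.arange(n_pos) + 0.5) / n_pos)
    w = np.concatenate([neg, -pos * neg.sum() / pos.sum()])
    return w * (amplitude_v / np.max(np.abs(w)))


def generate_spike_train(rate_profile: np.ndarray, fs: float,
                         refractory_s: float = 0.0,
                         seed: int | np.random.Generator = 0) -> np.ndarray:
    """Inhomogeneous-Poisson spike times by thinning, with an optional
    dead-time pass (earlier spike wins).

    ``rate_profile`` holds instantaneous rates (Hz) sampled at ``fs``; the
    realized process is piecewise-constant between samples.
    """
    rate = np.asarray(rate_profile, dtype=np.float64)
    if np.any(rate < 0):
        raise ValueError("rates must be non-negative")
    if refractory_s < 0:
        raise ValueError("refractory_s must be >= 0")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    duration = len(rate) / fs
    rmax = float(rate.max(initial=0.0))
    if rmax == 0.0 or duration == 0.0:
        return np.empty(0)
    n = rng.poisson(rmax * duration)
    times = np.sort(rng.uniform(0.0, duration, n))
    local = rate[np.minimum((times * fs).astype(int), len(rate) - 1)]
    times = times[rng.uniform(0.0, rmax, n) < local]
    if refractory_s > 0 and len(times) > 1:
        kept = [times[0]]
        for t in times[1:]:
            if t - kept[-1] >= refractory_s:
                kept.append(t)
        times = np.array(kept)
    return times


def render_signal(spike_times: np.ndarray, template: np.ndarray,
                  duration_s: float, fs: float,
                  amplitudes: np.ndarray | None = None) -> np.ndarray:
    """Superpose a waveform at each spike time on a zero baseline.

    The template is placed starting at the spike's sample index; a spike at
    or beyond ``duration_s`` is rejected.  ``amplitudes`` optionally scales
    the template per spike.
    """
    n = int(round(duration_s * fs))
    spike_times = np.asarray(spike_times, dtype=np.float64)
    if np.any((spike_times < 0) | (spike_times >= duration_s)):
        raise ValueError("spike times must lie in [0, duration_s)")
    out = np.zeros(n)
    amps = (np.ones(len(spike_times)) if amplitudes is None
            else np.asarray(amplitudes, dtype=np.float64))
    for t, a in zip(spike_times, amps):
        i = int(round(t * fs))
        seg = template[: n - i]
        out[i:i + len(seg)] += a * seg
    return out


def add_noise(signal: np.ndarray, noise_model: str, noise_sigma: float,
              seed: int | np.random.Generator = 0, fs: float = 24414.0,
              return_info: bool = False):
    """Additive recording noise.

    Models: ``white`` (Gaussian); ``white+pink`` (70/30 variance split with
    a 1/f component, a stand-in for biological background); and
    ``white+artifact_bursts`` (white noise plus sporadic 100 ms epochs of
    3x extra noise, a stand-in for movement/chewing artifacts).  With
    ``return_info=True`` the burst intervals are returned alongside.
    """
    if noise_sigma < 0:
        raise ValueError("noise_sigma must be >= 0")
    x = np.asarray(signal, dtype=np.float64)
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    info: dict = {"burst_intervals": []}
    if noise_sigma == 0.0:
        out = x.copy()
        return (out, info) if return_info else out
    n = len(x)
    if noise_model == "white":
        noise = noise_sigma * rng.standard_normal(n)
    elif noise_model == "white+pink":
        white = rng.standard_normal(n)
        spec = np.fft.rfft(rng.standard_normal(n))
        f = np.fft.rfftfreq(n, d=1.0 / fs)
        scale = np.zeros_like(f)
        scale[1:] = 1.0 / np.sqrt(f[1:])
        pink = np.fft.irfft(spec * scale, n)
        pink /= pink.std()
        noise = noise_sigma * (np.sqrt(0.7) * white + np.sqrt(0.3) * pink)
    elif noise_model == "white+artifact_bursts":
        noise = noise_sigma * rng.standard_normal(n)
        duration = n / fs
        n_bursts = rng.poisson(0.2 * duration)
        starts = np.sort(rng.uniform(0.0, max(duration - 0.1, 0.0),
                                     n_bursts))
        for t0 in starts:
            i0, i1 = int(t0 * fs), min(int((t0 + 0.1) * fs), n)
            noise[i0:i1] += 3.0 * noise_sigma * rng.standard_normal(i1 - i0)
            info["burst_intervals"].append((t0, t0 + 0.1))
    else:
        raise ValueError(f"unknown noise model {noise_model!r}")
    out = x + noise
    return (out, info) if return_info else out


def generate_behavior(config: SessionConfig,
                      seed: int | np.random.Generator | None = None
                      ) -> BehavioralLog:
    """Event log of the paddle protocol.

    Per trial: protract, three self-paced hits, retract shortly after the
    third hit, then a 9 s retraction gap.  A ``failure_fraction`` of trials
    is flagged unaccepted (alternating non-preferred-limb / premature-hit
    reasons) and a ``short_pair_fraction`` of accepted trials contains one
    inter-hit gap below 200 ms.
    """
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(config.seed if seed is None else seed))
    rows = []
    t = config.lead_in_s
    failure_kinds = ("non_preferred_limb", "premature_hit")
    n_fail = 0
    for trial in range(config.n_trials):
        failed = rng.uniform() < config.failure_fraction
        reason = failure_kinds[n_fail % 2] if failed else ""
        n_fail += failed
        accepted = not failed
        rows.append((t, "protract", trial, accepted, reason))
        t_hit = t + rng.uniform(*config.hit_latency_range_s)
        gaps = rng.uniform(*config.inter_hit_range_s, size=2)
        if (not failed) and rng.uniform() < config.short_pair_fraction:
            gaps[rng.integers(2)] = rng.uniform(0.08, 0.19)
        for g in (0.0, *gaps):
            t_hit += g
            rows.append((t_hit, "hit", trial, accepted, reason))
        t = t_hit + config.retract_delay_s
        rows.append((t, "retract", trial, accepted, reason))
        t += config.retraction_s
    if config.duration_s is not None and t > config.duration_s:
        raise ValueError(
            f"protocol needs {t:.1f} s but duration_s = {config.duration_s}"
        )
    ev = pd.DataFrame(rows, columns=["time_s", "event_type", "trial_id",
                                     "accepted_flag", "failure_reason"])
    return BehavioralLog(events=ev)


def _rate_profiles(config: SessionConfig, log: BehavioralLog,
                   duration_s: float) -> np.ndarray:
    n = int(round(duration_s * _RATE_FS))
    cats = config.categories()
    profiles = np.full((config.n_channels, n), config.baseline_rate_hz)
    hit_times = log.hits()["time_s"].to_numpy()
    for ch, cat in enumerate(cats):
        if cat not in _MOVEMENT_CATEGORIES:
            continue
        for t_hit in hit_times:
            i0 = int(round((t_hit + config.premovement_onset_ms / 1e3)
                           * _RATE_FS))
            i1 = int(round(t_hit * _RATE_FS))
            profiles[ch, max(i0, 0):max(i1, 0)] = (
                config.baseline_rate_hz * config.hit_modulation)
    return profiles


def _background_epochs(log: BehavioralLog, t_end: float,
                       engage_s: float = 0.5) -> list[tuple[float, float]]:
    """Spans of elevated broadband background: from each retraction (and
    from the session start) until ``engage_s`` before the next trial's
    first hit -- the roaming/chewing transition time between hitting
    sequences.  The pre-hit engagement period itself stays at baseline."""
    first_hits = (log.hits().groupby("trial_id")["time_s"].min()
                  .sort_values().to_numpy())
    retracts = log.events.loc[log.events["event_type"] == "retract",
                              "time_s"].to_numpy()
    spans, start = [], 0.0
    for t_hit in first_hits:
        stop = max(t_hit - engage_s, start)
        spans.append((start, stop))
        later = retracts[retracts >= t_hit]
        if len(later) == 0:
            return spans
        start = float(later[0])
    spans.append((start, t_end))
    return spans


def generate_session(config: SessionConfig
                     ) -> tuple[RecordingSession, BehavioralLog, GroundTruth]:
    """Compose behavior, spike trains, waveforms and noise into a session.

    Movement-category channels carry the pre-hit rate elevation; the noise
    amplitude is multiplied by ``nohit_background_gain`` between hitting
    sequences (from each retraction until 0.5 s before the next trial's
    first hit), in a random ``background_elevated_prob`` fraction of those
    epochs.  Manual thresholds (for fixed-threshold analysis) are the
    true 4-sigma level biased upward by ``manual_threshold_bias``,
    emulating a once-per-session visual estimate.  Fully reproducible from
    ``config.seed``.
    """
    ss = np.random.SeedSequence(config.seed)
    rng_beh, rng_units, rng_noise, rng_bg = (np.random.default_rng(s)
                                             for s in ss.spawn(4))
    log = generate_behavior(config, seed=rng_beh)
    t_last = float(log.events["time_s"].iloc[-1])
    duration = config.duration_s or (t_last + 1.0)
    n = int(round(duration * config.fs))

    profiles = _rate_profiles(config, log, duration)
    template = make_template(config.fs, config.spike_amplitude_v)

    signals = np.zeros((config.n_channels, n), dtype=np.float64)
    all_times: list[np.ndarray] = []
    for ch in range(config.n_channels):
        n_units = int(rng_units.integers(config.units_per_channel[0],
                                         config.units_per_channel[1] + 1))
        unit_amp = rng_units.uniform(0.5, 1.0, n_units)
        times, amps = [], []
        for u in range(n_units):
            t_u = generate_spike_train(profiles[ch] / n_units, _RATE_FS,
                                       refractory_s=0.0, seed=rng_units)
            jit = 1.0 + config.amplitude_jitter * rng_units.standard_normal(
                len(t_u))
            times.append(t_u)
            amps.append(unit_amp[u] * np.clip(jit, 0.2, None))
        times = np.concatenate(times)
        amps = np.concatenate(amps)
        order = np.argsort(times)
        times, amps = times[order], amps[order]
        # merged-train dead time: keep the earlier spike
        if config.refractory_s > 0 and len(times) > 1:
            keep = np.zeros(len(times), dtype=bool)
            keep[0] = True
            last = times[0]
            for i in range(1, len(times)):
                if times[i] - last >= config.refractory_s:
                    keep[i] = True
                    last = times[i]
            times, amps = times[keep], amps[keep]
        # quantize to the sample grid so truth and rendering agree exactly
        idx = np.minimum(np.round(times * config.fs).astype(int), n - 1)
        times = idx / config.fs
        times, uniq = np.unique(times, return_index=True)
        amps = amps[uniq]
        signals[ch] = render_signal(times, template, duration, config.fs,
                                    amplitudes=amps)
        all_times.append(times)

    raw_noise, info = add_noise(np.zeros(n), config.noise_model,
                                config.noise_sigma_v, seed=rng_noise,
                                fs=config.fs, return_info=True)
    # higher broadband background between hitting sequences -- but only
    # "typically": each inter-trial epoch is elevated with a configurable
    # probability, so the background is a nuisance, not a clean label
    gain = np.ones(n)
    for t0, t1 in _background_epochs(log, duration):
        if rng_bg.uniform() < config.background_elevated_prob:
            gain[int(t0 * config.fs):int(t1 * config.fs)] = (
                config.nohit_background_gain)
    signals += raw_noise * gain

    thr = 4.0 * config.noise_sigma_v * (1.0 + config.manual_threshold_bias)
    session = RecordingSession(
        fs=config.fs,
        signals=signals.astype(np.float32),
        channel_categories=config.categories(),
        manual_thresholds=np.full(config.n_channels, thr),
    )
    truth = GroundTruth(
        spike_times=all_times,
        rate_fs=_RATE_FS,
        rate_profiles=profiles,
        template=template,
        template_peak_v=float(np.max(np.abs(template))),
        polarity="negative",
        noise_sigma_true=config.noise_sigma_v,
        burst_intervals=info["burst_intervals"],
    )
    return session, log, truth


def replace_config(config: SessionConfig, **kwargs) -> SessionConfig:
    """Convenience wrapper around dataclasses.replace."""
    return replace(config, **kwargs)
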