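"""End-to-end orchestration of the three analysis cases.

Case A: adaptive (median-based) spike detection on the raw signal.
Case B: wavelet soft-threshold denoising, then adaptive detection.
Case C: manual fixed-threshold detection on the raw signal (the routine
        practice the adaptive approach is compared against).

Every case then runs the same tail: paw-channel spike-count features around
each accepted trial's first hit, and a stratified five-fold QDA
cross-validation.  Case B is typically swept over the full grid of 10
mother wavelets x 10 threshold correction factors (gamma in [0.4, 2]); the
grid shares one CV seed so cells differ only by the denoising.  Session
errors are compared across cases with a one-way ANOVA.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.stats import f_oneway

from ._filters import WAVELETS
from .classify import EvalResult, crossval_5fold
from .denoise import (DenoiseConfig, estimate_noise_sigma_qq, snr_estim,
                      threshold_coeffs, wavelet_threshold)
from .detect import DetectConfig, SpikeTrain, detect_spikes
from .features import WindowSpec, build_dataset, select_trials
from .io import BehavioralLog, RecordingSession
from .synth import generate_session
from .wavelets import wavedec, waverec

__all__ = [
    "CaseSpec",
    "CaseRun",
    "GridResult",
    "run_case",
    "grid_search_caseB",
    "anova_oneway",
    "run_experiment",
    "format_report",
    "GAMMA_GRID",
]

logger = logging.getLogger("muhit")

#: Ten threshold correction factors, evenly spaced over the stated range.
GAMMA_GRID = tuple(np.linspace(0.4, 2.0, 10))


@dataclass(frozen=True)
class CaseSpec:
    """One analysis recipe.  ``denoise`` is required for Case B; Case C
    takes its per-channel thresholds from the session metadata."""

    case: str = "A"
    denoise: DenoiseConfig | None = None
    detect: DetectConfig = field(default_factory=DetectConfig)
    windows: WindowSpec = field(default_factory=WindowSpec)
    cv_seed: int = 0
    regularization: float = 1e-6

    def __post_init__(self):
        if self.case not in ("A", "B", "C"):
            raise ValueError("case must be 'A', 'B' or 'C'")
        if self.case == "B" and self.denoise is None:
            raise ValueError("Case B requires a DenoiseConfig")


@dataclass
class CaseRun:
    """Evaluation plus stage summaries of one case on one session."""

    case: str
    eval_result: EvalResult
    spike_counts: list[int]
    snr_before_db: float | None = None
    snr_after_db: float | None = None

    @property
    def error_pct(self) -> float:
        return self.eval_result.mean_error_pct

    @property
    def accuracy_pct(self) -> float:
        return self.eval_result.accuracy_pct


@dataclass
class GridResult:
    """Case B error surface over (wavelet, gamma)."""

    wavelets: tuple
    gammas: tuple
    error_pct: np.ndarray          # (n_wavelets, n_gammas)
    best_wavelet: str
    best_gamma: float
    min_error_pct: float

    @classmethod
    def from_matrix(cls, wavelets, gammas, error_pct) -> "GridResult":
        error_pct = np.asarray(error_pct, dtype=np.float64)
        # first minimal cell in wavelet-major scan order
        i, j = np.unravel_index(int(np.argmin(error_pct)), error_pct.shape)
        return cls(wavelets=tuple(wavelets), gammas=tuple(gammas),
                   error_pct=error_pct, best_wavelet=wavelets[i],
                   best_gamma=float(gammas[j]),
                   min_error_pct=float(error_pct[i, j]))


def _detect_all(signals: np.ndarray, fs: float, spec: CaseSpec,
                manual_thresholds=None) -> list[SpikeTrain]:
    trains = []
    for ch in range(signals.shape[0]):
        cfg = spec.detect
        if spec.case == "C":
            cfg = replace(cfg, mode="manual",
                          manual_threshold=float(manual_thresholds[ch]))
        trains.append(detect_spikes(signals[ch], fs, cfg, channel=ch))
    return trains


def _mean_hit_window_snr(signals: np.ndarray, fs: float,
                         hit_times, channels,
                         window_s: float = 0.400) -> float:
    vals = []
    for t in hit_times:
        i1 = int(round(t * fs))
        i0 = max(i1 - int(round(window_s * fs)), 0)
        for ch in channels:
            est = snr_estim(signals[ch, i0:i1])
            if est.valid:
                vals.append(est.snr_db)
    return float(np.mean(vals)) if vals else float("nan")


def run_case(session: RecordingSession, log: BehavioralLog,
             spec: CaseSpec, compute_snr: bool = True) -> CaseRun:
    """Execute one case's stage sequence on one session."""
    if spec.case == "C":
        if session.manual_thresholds is None or np.any(
                np.isnan(session.manual_thresholds)):
            raise ValueError("Case C requires manual thresholds for every "
                             "channel in the session metadata")
    signals = session.signals.astype(np.float64)
    snr_before = snr_after = None
    if spec.case == "B":
        hit_times = sorted(select_trials(log).values())
        paw = session.paw_channels()
        if compute_snr:
            snr_before = _mean_hit_window_snr(signals, session.fs,
                                              hit_times, paw)
        signals = np.stack([
            _denoise_channel(signals[ch], spec.denoise)
            for ch in range(signals.shape[0])
        ])
        if compute_snr:
            snr_after = _mean_hit_window_snr(signals, session.fs,
                                             hit_times, paw)
    trains = _detect_all(signals, session.fs, spec,
                         session.manual_thresholds)
    dataset = build_dataset(trains, log, spec.windows,
                            session.paw_channels())
    result = crossval_5fold(dataset.X, dataset.y, seed=spec.cv_seed,
                            regularization=spec.regularization)
    run = CaseRun(case=spec.case, eval_result=result,
                  spike_counts=[len(t) for t in trains],
                  snr_before_db=snr_before, snr_after_db=snr_after)
    logger.info(
        "case %s: %d trials, spikes/channel %s, error %.1f%%%s",
        spec.case, dataset.X.shape[0] // 2, run.spike_counts,
        run.error_pct,
        (f", SNR {snr_before:.1f} -> {snr_after:.1f} dB"
         if snr_before is not None and snr_after is not None else ""),
    )
    return run


def _denoise_channel(x: np.ndarray, cfg: DenoiseConfig,
                     sigma: float | None = None) -> np.ndarray:
    if sigma is None:
        sigma = estimate_noise_sigma_qq(x)
    Th = wavelet_threshold(sigma, cfg.gamma, len(x))
    return waverec(threshold_coeffs(wavedec(x, cfg.wavelet, cfg.levels), Th))


def grid_search_caseB(session: RecordingSession, log: BehavioralLog,
                      spec: CaseSpec, wavelets=WAVELETS,
                      gammas=GAMMA_GRID) -> GridResult:
    """Full (wavelet x gamma) Case B evaluation with a shared CV seed.

    The per-channel DWT is computed once per wavelet and the noise sigma
    once per channel, so a grid cell costs one soft-threshold pass, one
    inverse transform and one detection/classification tail; the cell
    result is identical to an independent :func:`run_case` call with that
    DenoiseConfig.
    """
    signals = session.signals.astype(np.float64)
    fs = session.fs
    paw = session.paw_channels()
    n_ch = signals.shape[0]
    sigma = [estimate_noise_sigma_qq(signals[ch]) for ch in range(n_ch)]
    errors = np.empty((len(wavelets), len(gammas)))
    base_spec = CaseSpec(case="A", detect=spec.detect, windows=spec.windows,
                         cv_seed=spec.cv_seed,
                         regularization=spec.regularization)
    for i, w in enumerate(wavelets):
        coeffs = [wavedec(signals[ch], w, 5) for ch in range(n_ch)]
        for j, g in enumerate(gammas):
            den = np.stack([
                waverec(threshold_coeffs(
                    coeffs[ch],
                    wavelet_threshold(sigma[ch], g, signals.shape[1])))
                for ch in range(n_ch)
            ])
            trains = _detect_all(den, fs, base_spec)
            dataset = build_dataset(trains, log, spec.windows, paw)
            res = crossval_5fold(dataset.X, dataset.y, seed=spec.cv_seed,
                                 regularization=spec.regularization)
            errors[i, j] = res.mean_error_pct
    return GridResult.from_matrix(wavelets, gammas, errors)


def anova_oneway(*groups) -> tuple[float, float]:
    """Classical one-way ANOVA across groups of per-session errors.

    Returns (F, p).  Needs >= 2 groups with >= 2 values each; fully
    constant input (no variance anywhere) is rejected as degenerate.
    """
    if len(groups) == 1 and isinstance(groups[0], (list, tuple)) and \
            len(groups[0]) and isinstance(groups[0][0], (list, tuple,
                                                         np.ndarray)):
        groups = tuple(groups[0])
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    arrays = [np.asarray(g, dtype=np.float64) for g in groups]
    if any(len(a) < 2 for a in arrays):
        raise ValueError("every group needs at least two values")
    allv = np.concatenate(arrays)
    if np.all(allv == allv[0]):
        raise ValueError("degenerate input: all values identical")
    res = f_oneway(*arrays)
    return float(res.statistic), float(res.pvalue)


def run_experiment(session_configs, seed: int = 0,
                   windows: WindowSpec | None = None,
                   wavelets=WAVELETS, gammas=GAMMA_GRID,
                   compute_snr: bool = False) -> dict:
    """Multi-session A/B/C comparison.

    For each session config: generate the session, run Case A, the full
    Case B grid (reporting its minimum), and Case C.  Returns a
    machine-readable report with per-session errors, across-session means
    and standard deviations, and one-way ANOVAs of A vs B and B vs C.
    Deterministic for fixed configs and seed.
    """
    windows = windows or WindowSpec()
    sessions = []
    err_A, err_B, err_C = [], [], []
    for k, cfg in enumerate(session_configs):
        session, log, _ = generate_session(cfg)
        spec = CaseSpec(case="A", windows=windows, cv_seed=seed)
        a = run_case(session, log, spec, compute_snr=False)
        grid = grid_search_caseB(session, log, spec, wavelets=wavelets,
                                 gammas=gammas)
        c = run_case(session, log, replace(spec, case="C"),
                     compute_snr=False)
        sessions.append({
            "config_seed": cfg.seed,
            "error_A_pct": a.error_pct,
            "error_B_min_pct": grid.min_error_pct,
            "error_C_pct": c.error_pct,
            "best_wavelet": grid.best_wavelet,
            "best_gamma": grid.best_gamma,
            "spike_counts_A": a.spike_counts,
        })
        err_A.append(a.error_pct)
        err_B.append(grid.min_error_pct)
        err_C.append(c.error_pct)
    report = {
        "seed": seed,
        "n_sessions": len(sessions),
        "sessions": sessions,
        "summary": {
            case: {"mean_error_pct": float(np.mean(e)),
                   "sd_error_pct": float(np.std(e, ddof=1))
                   if len(e) > 1 else 0.0,
                   "mean_accuracy_pct": float(100.0 - np.mean(e))}
            for case, e in (("A", err_A), ("B", err_B), ("C", err_C))
        },
    }
    if len(err_A) >= 2:
        f_ab, p_ab = anova_oneway(err_A, err_B)
        f_bc, p_bc = anova_oneway(err_B, err_C)
        report["anova"] = {"A_vs_B": {"F": f_ab, "p": p_ab},
                           "B_vs_C": {"F": f_bc, "p": p_bc}}
    return report


def format_report(report: dict) -> str:
    """Human-readable table of a run_experiment report."""
    lines = [f"{'session':>8} {'err A %':>8} {'err B %':>8} {'err C %':>8} "
             f"{'best wavelet':>12} {'gamma':>6}"]
    for s in report["sessions"]:
        lines.append(
            f"{s['config_seed']:>8} {s['error_A_pct']:>8.1f} "
            f"{s['error_B_min_pct']:>8.1f} {s['error_C_pct']:>8.1f} "
            f"{s['best_wavelet']:>12} {s['best_gamma']:>6.2f}"
        )
    lines.append("")
    for case in ("A", "B", "C"):
        m = report["summary"][case]
        lines.append(
            f"Case {case}: error {m['mean_error_pct']:.1f} +/- "
            f"{m['sd_error_pct']:.1f} %  (accuracy "
            f"{m['mean_accuracy_pct']:.1f} %)"
        )
    if "anova" in report:
        a = report["anova"]
        lines.append(
            f"ANOVA  A vs B: F = {a['A_vs_B']['F']:.2f}, "
            f"p = {a['A_vs_B']['p']:.4f};  B vs C: F = "
            f"{a['B_vs_C']['F']:.2f}, p = {a['B_vs_C']['p']:.4f}"
        )
    return "\n".join(lines)
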