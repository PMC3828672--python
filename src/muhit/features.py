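"""Trial selection and spike-count feature extraction.

Each accepted trial contributes a balanced pair of observations: a "hit"
vector of spike counts in three consecutive 120 ms intervals preceding the
paddle hit, and a "no-hit" vector from three equal intervals further back,
in the lull between hitting sequences.  Only the first hit of a successful
three-hit trial is used; trials are discarded when flagged as failures
(non-preferred limb, premature hit) or when two of their hits fall closer
than 200 ms, which would blur the per-hit neural signature.

Interval placement (relative to the hit timestamp, default "gap40"
anchoring): hit bins [-400, -280), [-280, -160), [-160, -40) ms -- ending
40 ms short of contact, since forelimb muscle activity begins roughly
300 ms before a reach and the cortical lead precedes that; no-hit bins are
the same pattern shifted 500 ms earlier, [-900, -540).  "Up to -400 ms
before the hit" admits two natural anchorings, so the alternative "flush"
placement ([-360, 0) and [-860, -500)) is available behind the same
switch rather than decided silently.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .detect import SpikeTrain, count_in_interval
from .io import BehavioralLog

__all__ = [
    "WindowSpec",
    "TrialFeatures",
    "FeatureDataset",
    "select_trials",
    "extract_features",
    "build_dataset",
    "LABEL_HIT",
    "LABEL_NOHIT",
]

logger = logging.getLogger("muhit")

LABEL_HIT = 1
LABEL_NOHIT = 0

MIN_INTER_HIT_S = 0.200


@dataclass(frozen=True)
class WindowSpec:
    """Bin edges (ms, relative to the hit) for the two label windows.

    Four edges define three contiguous 120 ms bins for each label; the two
    spans must be disjoint.
    """

    hit_edges_ms: tuple = (-400.0, -280.0, -160.0, -40.0)
    nohit_edges_ms: tuple = (-900.0, -780.0, -660.0, -540.0)

    def __post_init__(self):
        for edges in (self.hit_edges_ms, self.nohit_edges_ms):
            if len(edges) != 4:
                raise ValueError("each label window needs 4 bin edges")
            widths = np.diff(edges)
            if not np.allclose(widths, 120.0):
                raise ValueError("bins must be exactly 120 ms wide")
        if self.nohit_edges_ms[-1] > self.hit_edges_ms[0]:
            raise ValueError("hit and no-hit spans must be disjoint")

    @classmethod
    def flush(cls) -> "WindowSpec":
        """Alternative anchoring with the hit window ending at the hit."""
        return cls(hit_edges_ms=(-360.0, -240.0, -120.0, 0.0),
                   nohit_edges_ms=(-860.0, -740.0, -620.0, -500.0))

    @property
    def earliest_offset_s(self) -> float:
        return self.nohit_edges_ms[0] / 1e3

    def bins_s(self, label: int) -> list[tuple[float, float]]:
        edges = self.hit_edges_ms if label == LABEL_HIT else self.nohit_edges_ms
        return [(edges[i] / 1e3, edges[i + 1] / 1e3) for i in range(3)]


@dataclass
class TrialFeatures:
    """Counts matrix (selected channels x 3 intervals) for one trial and
    one label."""

    trial_id: int
    label: int
    channels: np.ndarray
    counts: np.ndarray

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=np.int64)
        self.channels = np.asarray(self.channels, dtype=np.int64)
        if self.counts.shape != (len(self.channels), 3):
            raise ValueError("counts must be (n_channels, 3)")
        if np.any(self.counts < 0):
            raise ValueError("spike counts cannot be negative")


@dataclass
class FeatureDataset:
    """Balanced design matrix: one hit and one no-hit row per trial.

    Columns are channel-major then interval: (ch_a int1, ch_a int2,
    ch_a int3, ch_b int1, ...).
    """

    X: np.ndarray
    y: np.ndarray
    trial_ids: np.ndarray
    channels: np.ndarray
    dropped_trials: list = field(default_factory=list)

    def iter_rows(self):
        n_ch = len(self.channels)
        for xi, yi, tid in zip(self.X, self.y, self.trial_ids):
            label = "hit" if yi == LABEL_HIT else "nohit"
            yield tid, label, xi.reshape(n_ch, 3), self.channels


def select_trials(log: BehavioralLog) -> dict[int, float]:
    """First-hit time of every accepted trial, keyed by trial id.

    A trial is accepted when it is not failure-flagged, groups exactly
    three hits, and no two of its hits are closer than 200 ms.
    """
    hits = log.hits()
    out: dict[int, float] = {}
    for tid, grp in hits.groupby("trial_id"):
        t = np.sort(grp["time_s"].to_numpy())
        if len(t) != 3:
            continue
        if not grp["accepted_flag"].all():
            continue
        if np.any(np.diff(t) < MIN_INTER_HIT_S):
            continue
        out[int(tid)] = float(t[0])
    return out


def extract_features(trains: list[SpikeTrain], hit_time: float,
                     spec: WindowSpec, channels,
                     trial_id: int = 0) -> tuple[TrialFeatures, TrialFeatures]:
    """Hit and no-hit count matrices for one trial.

    ``channels`` are indices into ``trains`` (the paw-responsive channels).
    The hit must lie at least ``-spec.earliest_offset_s`` into the
    recording so the no-hit window exists.
    """
    if hit_time + spec.earliest_offset_s < 0:
        raise ValueError(
            f"hit at {hit_time:.3f} s: no-hit window precedes recording start"
        )
    channels = np.asarray(channels, dtype=int)
    out = []
    for label in (LABEL_HIT, LABEL_NOHIT):
        counts = np.zeros((len(channels), 3), dtype=np.int64)
        for ci, ch in enumerate(channels):
            for bi, (a, b) in enumerate(spec.bins_s(label)):
                counts[ci, bi] = count_in_interval(
                    trains[ch], hit_time + a, hit_time + b)
        out.append(TrialFeatures(trial_id=trial_id, label=label,
                                 channels=channels, counts=counts))
    return out[0], out[1]


def build_dataset(trains: list[SpikeTrain], log: BehavioralLog,
                  spec: WindowSpec, paw_channels) -> FeatureDataset:
    """Balanced per-trial feature matrix over the paw channels.

    Trials whose no-hit window precedes the recording start are dropped
    (recorded in ``dropped_trials``).  Needs at least 2 accepted trials and
    at least one paw channel.
    """
    paw_channels = np.asarray(paw_channels, dtype=int)
    if len(paw_channels) == 0:
        raise ValueError("no paw-responsive channels: nothing to decode")
    selected = select_trials(log)
    rows_X, rows_y, rows_tid, dropped = [], [], [], []
    for tid, t_hit in sorted(selected.items()):
        if t_hit + spec.earliest_offset_s < 0:
            dropped.append((tid, "window precedes recording start"))
            logger.info("trial %d dropped: no-hit window precedes "
                        "recording start (hit at %.3f s)", tid, t_hit)
            continue
        hit_f, nohit_f = extract_features(trains, t_hit, spec,
                                          paw_channels, trial_id=tid)
        for f in (hit_f, nohit_f):
            rows_X.append(f.counts.ravel())   # channel-major, then interval
            rows_y.append(f.label)
            rows_tid.append(tid)
    if len(rows_X) < 4:
        raise ValueError(
            f"only {len(rows_X) // 2} usable trials; need at least 2"
        )
    return FeatureDataset(
        X=np.asarray(rows_X, dtype=np.int64),
        y=np.asarray(rows_y, dtype=np.int64),
        trial_ids=np.asarray(rows_tid, dtype=np.int64),
        channels=paw_channels,
        dropped_trials=dropped,
    )
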