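"""From spike trains to a cross-validated hit / no-hit decoder.

Each accepted trial contributes two rows: spike counts of the paw channels
in three 120 ms intervals before the first hit ("hit") and in three equal
intervals further back ("no-hit").  A quadratic discriminant is scored by
stratified five-fold cross-validation.
"""

import numpy as np

from muhit import (CaseSpec, DetectConfig, SessionConfig, WindowSpec,
                   build_dataset, crossval_5fold, detect_spikes,
                   generate_session)

cfg = SessionConfig(n_trials=24, seed=5)
session, log, truth = generate_session(cfg)

trains = [detect_spikes(session.signals[ch].astype(np.float64), session.fs,
                        DetectConfig(), channel=ch)
          for ch in range(session.n_channels)]

ds = build_dataset(trains, log, WindowSpec(), session.paw_channels())
print(f"dataset : {ds.X.shape[0]} rows x {ds.X.shape[1]} features "
      f"({len(ds.channels)} paw channels x 3 intervals)")
hit_mean = ds.X[ds.y == 1].mean(axis=0)
nohit_mean = ds.X[ds.y == 0].mean(axis=0)
print(f"mean counts per interval, hit   : {np.round(hit_mean, 1)}")
print(f"mean counts per interval, no-hit: {np.round(nohit_mean, 1)}")

res = crossval_5fold(ds.X, ds.y, seed=1)
print(f"5-fold QDA: error {res.mean_error_pct:.1f} %, "
      f"accuracy {res.accuracy_pct:.1f} %, "
      f"sensitivity {res.sensitivity_pct:.1f} %, "
      f"specificity {res.specificity_pct:.1f} %")

# The pre-hit firing-rate elevation on paw channels shows up as larger
# interval counts in the hit rows; the discriminant separates the two
# count distributions, and the fold metrics quantify how reliably.
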