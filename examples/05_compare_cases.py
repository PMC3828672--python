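"""The headline comparison: raw adaptive detection (A) vs wavelet
denoising + adaptive detection (B, best cell of the wavelet x gamma grid)
vs fixed manual thresholding (C), across seeded noisy sessions.

Uses a reduced grid (4 wavelets x 4 gammas) to keep the example fast; the
full 10 x 10 grid is what `grid_search_caseB` runs by default.
"""

from muhit import SessionConfig, format_report, run_experiment

configs = [SessionConfig.low_snr(seed=s, n_trials=8) for s in (1, 2, 3)]
report = run_experiment(configs, seed=7,
                        wavelets=("haar", "db6", "sym4", "coif2"),
                        gammas=(0.4, 0.6, 0.8, 1.2))
print(format_report(report))

# Case B's grid minimum should sit well below Case A: at 5-sigma spike
# amplitude the raw adaptive threshold misses small units, while after
# denoising the collapsed noise floor lets the (re-adapted) threshold
# recover them.  Case C suffers where the fixed level mismatches the
# fluctuating inter-trial background.
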