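"""Monte Carlo benchmark: how noise level affects each estimator.

Runs the noise preset at reduced scale (n=3 replications, M=2000) and
prints the per-condition summary with the bootstrap accuracy flag.
"""

from manifolddim import run_sweep

result = run_sweep("noise", scale={"n": 3, "M": 2000}, seed=1)
summary = result.summarize(n_boot=2000)
cols = ["alpha", "snr_db", "method", "mean", "sd", "accurate_rounded"]
print(summary[cols].to_string(index=False, float_format=lambda x: f"{x:.2f}"))
# Estimates inflate as SNR drops (20 -> 10 -> 7 dB), more steeply for the
# nonlinear (alpha=16) embedding; the accuracy flag marks conditions whose
# mean stays within half a dimension of the true d = 6.
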