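"""Score change-point detection before and after smoothing on a small grid.

Runs a reduced version of the synthetic benchmark: sinusoids with 2 random
phase shifts at two noise levels, 25 batches per cell.  Reports mean false
positives, false negatives and MCC per condition.  (The full protocol uses
200+ batches per cell, n = 1..4 and eight SNR levels.)
"""

import phasesmooth as ps

bcfg = ps.BenchmarkConfig(
    n_change_points=(2,), snr_grid=(0.05, 0.4), batches_per_cell=25, seed=5
)
res = ps.run_benchmark(bcfg)

print(res.table.to_string(index=False, float_format=lambda v: f"{v:.3f}"))
print()
print("At low SNR the raw residual is littered with spurious mean shifts")
print("(high FP); smoothing removes most of them at a small cost in missed")
print("true resets (FN), which raises the MCC.")
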