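"""Retrain correlation weights from scratch on the packaged table.

Trains the IIC-weighted target function on split 3 at the published
(threshold, epochs) = (1, 7) and prints the per-set metric battery.  The
Monte Carlo schedule is stochastic, so the numbers vary with the seed and
land in the vicinity of — not exactly on — the published statistics.
"""

import mcqsar as m

dataset = m.load_flavonols()
config = m.OptimizationConfig(threshold=1, epochs=7, seed=1, w_iic=0.2, n_runs=1)
result = m.optimize(dataset, "split3", config)

print(f"model: pIC50 = {result.model.c0:.3f} + {result.model.c1:.4f} x DCW(1, 7)")
print(f"{'set':6s} {'n':>3s} {'R2':>6s} {'CCC':>6s} {'IIC':>6s} {'s':>6s} {'MAE':>6s}")
for name, sm in result.report.sets.items():
    print(f"{name:6s} {sm.n:3d} {sm.r2:6.3f} {sm.ccc:6.3f} {sm.iic:6.3f} "
          f"{sm.s:6.3f} {sm.mae:6.3f}")
val = result.report.sets["VAL"]
print(f"VAL rm2 mean = {val.rm2_mean:.3f}, delta = {val.rm2_delta:.3f}; "
      f"Y-scrambling cRp2 = {result.report.crp2:.3f}")
print("\nA validation R2 near 0.7 with cRp2 well above 0.5 means the "
      "correlation is genuine, not a chance artifact of the descriptor.")
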