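"""Recover a planted structure-activity map from a synthetic library.

Generates 80 flavonol-like molecules whose activity is a known linear
function of attribute counts plus noise, trains three independent Monte
Carlo runs, and checks that the promoter classifier recovers the planted
signs — the end-to-end ground-truth test the real dataset cannot provide.
"""

import mcqsar as m

gen = m.GeneratorConfig(n_molecules=80, seed=0, noise_sigma=0.1)
opt = m.OptimizationConfig(threshold=1, epochs=40, seed=0, w_iic=0.2, n_runs=3)
report = m.recovery_experiment(gen, opt)

print("planted weights:")
for key, w in gen.planted_weights.items():
    recovered = report.sign_recovery[str(key)]
    print(f"  {key}: {w:+.2f} -> sign recovered: {recovered}")
print(f"validation R2 = {report.validation_r2:.3f}; "
      f"Y-scrambling cRp2 = {report.crp2:.3f}")
print("\nHigh validation R2 with correctly recovered signs shows the "
      "pipeline finds real structure, and cRp2 >> 0.5 that it is not chance.")
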