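"""Promoters of activity increase/decrease from weight stability.

Runs three independent Monte Carlo optimizations on the packaged table and
classifies each structural attribute by the stability of its correlation
weight's sign across runs — the model's mechanistic reading of which
chemistry drives anti-proliferative potency.
"""

import mcqsar as m

dataset = m.load_flavonols()
config = m.OptimizationConfig(threshold=1, epochs=7, seed=1, w_iic=0.2, n_runs=3)
results = m.optimize_runs(dataset, "split3", config)
promoters = m.extract_promoters([r.table for r in results], dataset, "split3")

increase = [p for p in promoters if p.classification == "increase"]
decrease = [p for p in promoters if p.classification == "decrease"]
print(f"{len(promoters)} attributes: {len(increase)} stable increase, "
      f"{len(decrease)} stable decrease")
print("\ntop stable promoters of increase (by |mean weight|):")
for p in increase[:8]:
    runs = " ".join(f"{w:+.2f}" for w in p.weights)
    gloss = f"  ({p.gloss})" if p.gloss else ""
    print(f"  {str(p.key):24s} [{runs}]  N_trn={p.n_trn}"
          f" defect={p.defect:.4f}{gloss}")
print("\nAttributes positive in every run are read as features a chemist "
      "could add to raise potency; unstable signs carry no interpretation.")
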