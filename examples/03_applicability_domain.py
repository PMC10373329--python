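"""Statistical-defect applicability domain on the packaged table.

Computes per-attribute defects from the training/calibration prevalence
split and flags molecules whose summed defect exceeds twice the training
average — the model's definition of an out-of-domain structure.  A
chlorinated analogue (the dataset contains no halogens) illustrates how
unseen attributes push a molecule out of the domain.
"""

import mcqsar as m

dataset = m.load_flavonols()
split = "split3"
profiles = m.dataset_profiles(dataset)
trn = dataset.subset(split, "TRN")
cal = dataset.subset(split, "CAL")
defects = m.defect_table(m.prevalence(profiles[r.id] for r in trn), len(trn),
                         m.prevalence(profiles[r.id] for r in cal), len(cal))

nitrogen = m.AttributeKey("SK", "N")
rec = defects[nitrogen]
print(f"aliphatic nitrogen: {rec.n_trn}/{len(trn)} TRN vs {rec.n_cal}/{len(cal)} "
      f"CAL -> defect {rec.defect:.4f}")

outsider = m.molecule_profile("chloro", "ClCCOC1=C(Oc2ccccc2C1=O)c3ccc(OC)c(OC)c3")
flags = m.domain_flags(list(profiles.values()) + [outsider],
                       [r.id for r in trn], defects)
n_out = sum(f.outlier for i, f in flags.items() if i != "chloro")
print(f"dataset molecules flagged out-of-domain: {n_out}/{len(dataset)}")
print(f"chloro analogue: defect {flags['chloro'].defect:.2f}, "
      f"out of domain: {flags['chloro'].outlier}")
print("\nEvery chlorine-bearing attribute is unseen in training (defect 1 "
      "each), so the analogue's prediction should not be trusted.")
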