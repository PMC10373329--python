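# Methods

## Data model

A dataset is an ordered table of compounds: id, SMILES, observed pIC50
(−log10 molar IC50; may be absent for prediction-only rows) and, for each
named split, a role in one of four sets — training (TRN, fits the weights
and the regression), invisible training (iTRN, enters the target function
but not the fit), calibration (CAL, detects overtraining and carries the
IIC) and validation (VAL, untouched until final assessment).  Role cells
accept the words or the compact markers `+ − # *`.

The packaged table (`mcqsar.dataset.load_flavonols`) holds 80 flavonol
derivatives assayed against PC-3 cells, pIC50 3.39–6.27, with three
independent splits of sizes 29/20/12/19, 30/19/11/20 and 30/18/12/20.  Six
additional congeners had been removed upstream as |error| > 3·s residual
outliers of preliminary models; the table ships without them, and
`residual_outliers` implements the same rule for new fits.  The published
per-split descriptor values and predictions ride along as reference
columns (`dcw_split*`, `pred_split*`); they are used for checking, never
for training.  The published interpretation table's prevalence counts are
internally inconsistent with the published split markers (e.g. split-2
invisible-training nitrogen count 11 printed vs 15 implied); where the two
disagree we follow the markers, whose set sizes match the published
statistics table exactly.

## Attributes

SMILES are tokenized over the organic-subset dialect the dataset uses
(aromatic lowercase, `Cl/Br/Si` as single tokens, digits 1–9 ring
closures, `( ) = # @`; bracket atoms, charges and isotopes are parse
errors).  Typographic whitespace inside printed SMILES is stripped.  Local
attributes are one key per token and one per adjacent token pair
(canonicalized by sorting the two texts, so string reversal changes
nothing).  Branch parentheses and ring digits count as tokens: the
tradition this model family follows treats every SMILES symbol as an
attribute.  Case is significant (`c` aromatic vs `C` aliphatic).

Global codes are presence flags — BOND (`= # @`), NOSP (N/O/S/P), HALO
(F/Cl/Br/I) — plus their three pairwise concatenations (PAIR) and united
code (HARD), the number of ring-closure pairings (Cmax, equal to the SSSR
ring count on this chemistry), and the nitrogen/oxygen atom counts
(Nmax/Omax) carried in the payload.  A standalone HALO key is emitted by
default and can be disabled (`include_halo=False`); it always remains
inside PAIR and HARD.

The hydrogen-suppressed graph is built by a minimal SMILES parser (ring
closures become edges; digit reuse after closure is allowed; aromatic
bonds are implied by two aromatic endpoints).  Per vertex we compute
Morgan extended connectivity of orders 1 and 2 (order 0 is the degree),
simple-path counts of exactly 2 and 3 edges (paths, not walks — pinned by
a brute-force enumeration oracle in the tests), and valence shells
(vertices at shortest-path distance exactly 2 and 3).  Each value, its
pairwise sum and absolute difference become element-tagged keys, so EC1=3
on nitrogen and on carbon are distinct attributes.  Rings come from the
minimum cycle basis (SSSR); only 5- and 6-membered rings generate keys,
classed by aromaticity and heteroatom presence with the class count in the
payload.  The graph code is cross-checked against RDKit (atom, bond and
SSSR counts) on the whole packaged table.

## Descriptor and optimizer

DCW is the multiplicity-weighted sum of weights over the molecule's keys;
global keys appear once.  Keys never seen in training contribute zero and
are counted as "unseen" (they surface in the applicability domain as unit
defects).  Prevalence is molecule presence, not occurrence multiplicity —
the convention that reproduces the published worked defects.  Keys with
training presence < T are blocked: weight pinned at zero, never perturbed.

Weights initialize as independent Uniform(0.1, 1.1) draws (the positive
start matches the positive published DCW magnitudes; configurable).  One
epoch visits every unblocked key in a seeded-shuffled order, adds a
Uniform(−0.5, 0.5) step to its weight, refits (C0, C1) by closed-form
univariate least squares on TRN, recomputes the target function, and keeps
the step only on strict improvement — ties reject, so the trajectory is
deterministic given the seed and TF is non-decreasing by construction.
`const` defaults to 0.1 (the balance penalty is conventionally small and
unpublished); `w_iic` defaults to 0.2.  With `w_iic = 0` the target is the
plain balance of correlation (TF1).  The IIC uses signed mean absolute
errors over negative and non-negative calibration residuals; if either
side is empty the IIC is zero.  Grid search over (T, N) selects by
calibration R² (TF1) or calibration IIC (TF2), ties broken toward smaller
N then smaller T; the selection statistic for the published models was not
stated, so this choice mirrors the calibration set's stated role.
Published training statistics are therefore reproduction targets of
opportunity, not contracts: the original optimization schedule and `const`
are unpublished, and retraining lands near, not on, the printed numbers.

Per-run seeds for multi-run interpretation derive from the base seed by an
affine map mod 2³¹; the epoch stream and the Y-scrambling stream use
offset seeds so reporting settings cannot perturb training.

## Validation battery

R² is reported as squared Pearson correlation for every set (the
convention of this model family); for external sets the
training-mean-referenced formula is additionally exposed as
`r2_train_mean`, removing the source ambiguity downstream.  Q² is
leave-one-out on TRN via the exact hat-matrix identity (no refitting).
CCC is standard Lin's concordance (the published formula's denominator is
typographically garbled).  s = √(SSres/n) per set (an n−2 variant is
available), F = R²(n−2)/(1−R²) on TRN.  Roy's rm² uses through-origin
regression of predicted on observed for r0², axes interchanged for the
primed variant; the axis convention is not stated in the source, so rm²
comparisons are soft.  Y-scrambling permutes training activities with the
descriptor held fixed, refits (C0, C1), and reports cRp² =
R·√(max(R² − R̄r², 0)) over 10 iterations by default (count unpublished);
the clamp covers the noise-only case where sampling noise pushes the mean
scrambled R² above the true one.  Model selection across splits follows
the highest validation mean rm², ties broken by validation R².

## Applicability domain

Attribute defect = |P_TRN − P_CAL| / (N_TRN + N_CAL) with P the presence
fraction and N the presence count; an attribute absent from training has
defect 1.  The interpretation of "probability of an attribute" as the
presence fraction is frozen by the published worked examples (19/29 vs
6/12 → 0.0062; 18/30 vs 7/11 → 0.0015).  A molecule's defect sums its
distinct keys once each; it is out of domain when the sum strictly exceeds
twice the training-set mean.  Domain flags are reported alongside
predictions; they exclude molecules from summary statistics only when
explicitly requested.

## Interpretation

An attribute unblocked in every one of ≥3 independent runs is classified
by sign unanimity: all weights positive → promoter of increase, all
negative → promoter of decrease, otherwise undefined; an exact zero is
treated as no sign evidence.  Records carry the per-set prevalence and the
defect, mirroring the published interpretation table, and a short
human-readable gloss for a few recurring attribute shapes.

## Synthetic libraries

The generator splices substituent tails (alkyl chains, branched alkyls,
dialkylamino and cyclic-amine tails) into three chromen-4-one cores
matching the modelled chemistry, guaranteeing valid SMILES without a
sanitization dependency.  Activity is planted as intercept + Σ weight ×
attribute count + Gaussian noise.  Defaults: n = 80, σ = 0.1 pIC50 units,
intercept 4.6, planted weights +1.10 on aliphatic nitrogen, +0.07 on
aliphatic carbon and −0.80 on the branch-carbon pair — chosen so the
default activity distribution spans ≈ 2.8–6.3 (emulating the study's
3.39–6.28) and so the planted map contains strong-positive, weak-positive
and strong-negative effects, keeping sign recovery well-posed despite the
descriptor's collinear key families.  Roles are allocated at exact
35/25/15/25 counts and shuffled, so all four sets are non-empty from n = 8.

What the generator does *not* emulate: assay noise structure beyond
i.i.d. Gaussian, activity cliffs, scaffold families outside the flavonol
core, and measurement censoring.  Passing recovery tests therefore shows
the pipeline recovers linear attribute-count structure under realistic
sizes and noise — not that real flavonol SAR is linear.

Recovery experiments run 40 epochs (hill-climb convergence at these
problem sizes) with 3 runs per library.  Two behaviours worth knowing:
with the IIC term active the optimizer deliberately trades training fit
for residual symmetry and plateaus below perfect validation R² even at
σ = 0, so the exact-recovery check uses TF1, which reaches R² ≈ 1 there;
and individual collinear keys can swap shares of a planted effect between
runs, which is exactly the instability the unanimity rule screens out.

## Numerical choices and degenerate inputs

Zero descriptor variance on TRN aborts optimization (and any candidate
step that would zero it is rejected).  Pearson correlation returns 0 when
either side is constant.  Empty residual sides give IIC 0.  Ties in grid
search and model selection break deterministically as stated above.
Problem sizes in the tests and the acceptance script — 80-molecule
libraries, 5 seeds × 3 runs × 40 epochs, a 7-epoch retrain of the packaged
split — were chosen as the smallest sizes at which the statistical claims
stabilize.

## Known limitations

The SMILES dialect covers exactly the modelled chemistry (no bracket
atoms, charges, stereo bonds beyond `@` presence flags).  The optimizer is
a plain greedy hill climb — no restarts, annealing or tempering — matching
the described procedure; it finds local optima by design.  Printed-value
comparisons use ±0.01 (two-decimal printing).  The six upstream outlier
compounds and the natural-flavonol prediction structures are not shipped:
the former were removed before the published table, the latter were never
printed as SMILES.
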