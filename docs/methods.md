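# Methods

## Problem and model

A single amino-acid substitution changes the folding free energy of a
protein by ΔΔG; the sign of that change is the biologically decisive
quantity (ΔΔG < 0: destabilization). `protstab` treats the task as binary
classification from sequence alone. A record is (sequence, 1-based site,
wild-type residue, mutant residue, pH, ΔΔG and/or label); the label rule is
ΔΔG < 0 → negative, otherwise → positive, so **ΔΔG exactly 0 counts as
positive** (non-destabilizing). This asymmetry at zero is a documented
convention, not an accident.

The classifier is a soft-margin SVM with the RBF kernel
K(x₁, x₂) = exp(−γ‖x₁ − x₂‖²). γ controls boundary smoothness, C the
error/margin trade-off; defaults γ = 0.8, C = 1.0 with window size w = 11
and the six-scale feature subset {A, Aa, B, Co, No, P}. No class weighting
is applied by default despite the 464:1016 imbalance of the emulated data
shape — unweighted training reproduces the characteristic SP ≫ SN
behaviour of this task; weighting is available via
`TrainConfig(class_weight=...)`. The libsvm solver is deterministic for
fixed data, so fits are reproducible without a stochastic seed; the
configured seed drives fold assignment.

## Encoding

Vector layout (feature-major): for each selected scale, the w window
residues' normalized values; then one mutant-block entry per scale; then
pH/14. Length w·f + f + 1. Conventions:

* **Window = wild-type sequence.** The mutant identity enters only through
  the mutant block. An alternative "delta" mode encodes
  (scale(mut) − scale(wt) + 1)/2 at the mutant slot instead; it is a config
  switch (`mutant_mode="delta"`), not the default, because the plain block
  is the least-committal encoding of the mutant identity.
* **Padding.** Window positions beyond the sequence ends take the neutral
  mid-scale value 0.5 on every scale.
* **Normalization.** Every scale is min–max mapped to [0, 1] once at
  registry load. RBF distances are scale-sensitive; raw scales span
  anything from ~0–1 (propensities) to 75–204 (molecular weight), and
  without normalization the largest-magnitude scale would dominate the
  kernel.
* **Unknown residues** (B, Z, X, ...) raise by default; an opt-in "mean"
  policy substitutes the scale mean. Silent substitution would hide data
  errors.

## Scale tables

Twenty bundled plain-text tables (code, class, source, description + 20
residue:value lines), classed 5 biochemical / 5 structural / 3 empirical /
7 other. Values were transcribed from the cited ProtScale/CRC-style
sources; minor numeric deviations from the original publications are
possible and do not affect any package contract (all tests are invariant
to the exact values except the molecular-weight minimum at glycine). Two
special cases:

* Side-chain pKa assigns 7.00 to non-ionizable side chains — a neutral
  placeholder the source literature does not define.
* The three empirical protein-stability scales (S1, S2, S3) could not be
  redistributed; the bundled files are **synthetic stand-ins** (so labelled
  in filename and header) constructed to reproduce the qualitative ordering
  — buried hydrophobics stabilizing, charged/Gly/Pro destabilizing — not
  the published numbers. Conclusions that depend on the numeric identity of
  S1–S3 should not be drawn from this package.

## Evaluation protocol

Stratified, seeded 5-fold cross-validation; per-class fold sizes differ by
at most one. Metrics are computed **once on the pooled out-of-fold
predictions**, never averaged over folds — pooling changes MCC and AUC and
is load-bearing for comparability of subset searches. Definitions: AC, SN,
SP as percentages of the confusion cells; ST = (SN + SP)/2 exactly; MCC
with the 0-denominator convention MCC = 0; SN/SP undefined (reported as
None, never 0) when a class is absent. The ROC sweep emits one point per
distinct score (ties move together) plus the (0,0) endpoint; AUC is the
trapezoid area, which under this tie handling equals the Mann–Whitney pair
statistic with ties scored ½ (asserted against a brute-force pair-count
oracle in tests). Percentages are carried at full precision and rounded
half-even to 2 decimals only at rendering.

Confidence calibration: the pooled CV (score, label) pairs define a
threshold table (strictly decreasing thresholds; SN non-decreasing, SP
non-increasing). A positive call at score s gets 1 − SN at the nearest
threshold not exceeding s; a negative call 1 − SP at the nearest threshold
not below s. Decision value exactly 0 is classified positive, mirroring
the ΔΔG = 0 rule. Confidence always comes from the model's own CV scores —
decision-value scales differ across SVM solvers, so hard-coded thresholds
would be meaningless.

## Feature-subset search

Wrapper search under pooled-CV AUC, tie-broken by ST then lexicographic
subset. All candidates within one search share a single fold partition
(paired comparison; re-randomized folds would confound subset differences
with fold noise). The exhaustive search evaluates all C(n, k) subsets per
size up to `kmax` unless an evaluation budget would be exceeded, in which
case that size falls back to greedy forward selection and the result is
flagged approximate. The all-features classifier is always evaluated as a
control. Full pair search over 20 scales at n = 1480 takes on the order of
a minute; sizes ≥ 4 are hours-scale and are where the budget mechanism is
intended to bite.

## Synthetic benchmark

The generator emulates the *shape* of a curated thermodynamic mutation
dataset: random sequences (40 proteins × 120 residues), random
substitutions, pH uniform on [2, 10], n = 1480 records at the 464:1016
positive:negative ratio. The latent signal is

ΔΔG* = Σᵢ wᵢ·(scaleᵢ(mut) − scaleᵢ(wt)) + c·(mean window hydrophobicity − ½) + ε,
ε ~ N(0, σ²),

centred by its (1 − positive_fraction) quantile so the class ratio is hit
exactly; the recorded ΔΔG is the centred latent and labels follow the sign
rule. Acting through scale *differences* makes a correct mutant-aware
encoding necessary for recovery, so the generator is an integration test of
the encoding design, not just of the solver.

Defaults: planted pair {Co, No} with unit weights, σ = 0.3, no context
term. {Co, No} was chosen over more obvious pairs because planted-signal
recovery must be *identifiable*: a correlation analysis of Δ-scale signals
across all 190 scale pairs showed many pairs (e.g. bulkiness + composition)
are shadowed by proxy scales correlated with both members, whereas
composition + codon-number has a ~0.3 correlation margin over its best
proxy. At these defaults (verified by simulation before the tests were
frozen): planted-pair pooled AUC ≈ 0.93, single-feature ranking places both
planted scales above all 18 others, and the exhaustive pair search returns
the planted pair. The window-context study condition uses c = 8.0: the mean
window hydrophobicity has standard deviation ≈ 0.09 per unit weight, so
unit-scale weights are invisible; at 8.0 the context term carries enough
signal that an 11-residue window beats the bare site by ≈ 0.14 AUC.

What the generator does **not** emulate: real ΔΔG magnitudes or their
skewed distribution, protein families/homology structure, position-specific
conservation, or correlated measurement conditions. Passing the synthetic
recovery tests therefore demonstrates that the pipeline is correct and
sensitive, not that any particular accuracy will be achieved on
experimental data.

Null calibration is checked with the same pipeline and all signal weights
zeroed (labels from pure noise). Single pooled-CV null AUC draws at n = 600
scatter with sd ≈ 0.03 around chance, so the calibration test uses the mean
over ten fixed replicate seeds, which must lie in [0.43, 0.57].

## Problem sizes used in the test suite

Unit tests run on a 300-record generator draw; the end-to-end suite runs
the default n = 1480 benchmark for signal recovery (single-feature ranking
plus the full 190-pair exhaustive search), ten n = 600 null replicates, and
one n = 1480 context-signal sweep — about two minutes in total.

## Known limitations

* The redundancy of input datasets (sequence identity between proteins) is
  the caller's responsibility; no clustering/filtering is performed.
* Only the direction of the stability change is predicted, never the ΔΔG
  magnitude.
* Scales S1–S3 are stand-ins (above); the bundled tables generally are a
  data decision, replaceable by pointing `load_registry` at another
  directory in the same file format.
* Model persistence uses joblib archives with a format-version field;
  archives are not portable across incompatible scikit-learn versions.
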