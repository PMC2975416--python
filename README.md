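# protstab

Sequence-based prediction of the **direction of protein stability change**
upon a single amino-acid substitution.

Most disease-associated missense variants act by destabilizing the protein
they fall in, and the folding free-energy change ΔΔG of a substitution is
rarely measured. `protstab` addresses the binary form of the problem: given
only the protein sequence, a substitution (e.g. `G56S`), and the pH of
interest, predict whether the substitution **increases** (ΔΔG ≥ 0) or
**decreases** (ΔΔG < 0) protein stability, with a calibrated confidence.
It is intended for bioinformaticians triaging nsSNPs / candidate-gene
variants when no structure is available.

## Method

Each substitution record is encoded as a fixed-length vector

* a window of *w* consecutive residues centred on the substitution site
  (default *w* = 11; positions beyond the sequence ends are padded with a
  neutral mid-scale token), each residue encoded by one or more of twenty
  bundled amino-acid property scales (biochemical, structural, empirical,
  and other biological features; each min–max normalized to [0, 1]),
* a block with the mutant residue's values on the same scales, and
* the pH scaled by 1/14,

giving length *w·f + f + 1* for *f* scales. An RBF-kernel support-vector
machine, K(x₁, x₂) = exp(−γ‖x₁ − x₂‖²) with defaults γ = 0.8, C = 1.0, is
trained on labelled records (label = sign of ΔΔG). Performance is measured
by **pooled five-fold cross-validation**: the out-of-fold decision values of
all five folds are combined and the metrics — overall accuracy AC,
sensitivity SN, specificity SP, prediction strength ST = (SN + SP)/2,
Matthews correlation MCC, and ROC AUC — are computed once on the pooled
predictions. Feature subsets are chosen by wrapper search (single-feature
ranking, best-singles combinations, and budgeted exhaustive search) under
the pooled-CV AUC objective with a shared fold partition. Prediction
confidence is ROC-calibrated: for a query with decision value *s*,
confidence = 1 − SN(*s*) for a positive call and 1 − SP(*s*) for a negative
call, where SN/SP are the cross-validated rates with *s* as the threshold.

Because no curated experimental dataset ships with the package, a synthetic
generator (`protstab.synthetic`) produces mutation datasets with a planted
scale-difference signal and the realistic 464:1016 class imbalance, so the
whole pipeline is testable end-to-end.

## Worked example

```sh
# 1. a synthetic benchmark: 600 substitution records, TSV + FASTA
protstab simulate --out-prefix bench --n-instances 600 --seed 5
# wrote 600 instances (188 positive / 412 negative) to bench.tsv / bench.fasta

# 2. cross-validate, calibrate confidence, train, save
protstab train --dataset bench.tsv --features Co,No --window 11 \
               --model-out model.joblib
```

```text
Stability direction classifier (RBF-SVM)
==============================================
features:        Co, No
window size:     11
vector length:   25
gamma:           0.8
C:               1.0
training set:    600 instances (188 positive / 412 negative)
support vectors: 366
----------------------------------------------
pooled 5-fold cross-validation:
  AC  = 86.67 %
  SN  = 69.15 %
  SP  = 94.66 %
  ST  = 81.90 %
  MCC = 0.6805
  AUC = 0.9472
```

The CV block is the honest performance estimate: 86.67 % of pooled
out-of-fold calls were correct; the classifier is conservative about the
minority class (SN 69 % vs SP 95 %), and ST averages the two. AUC 0.947
summarizes the full threshold sweep.

```sh
# 3. predict a substitution on a new sequence
printf ">query\nMAGWTKLVSEPRRTIDYFG\n" > q.fasta
protstab predict --model model.joblib --fasta q.fasta --mutation G3S --ph 7.0
```

```text
query	substitution	result	confidence	decision_value
query	G3S	decreased stability	11.41%	-0.2808
```

G3S is called destabilizing, but weakly: the decision value −0.28 is close
to the boundary, and the ROC-calibrated confidence (1 − SP at that
threshold) is only 11 %.

The same objects are available as a library, statsmodels-style:

```python
import protstab as ps

ds = ps.read_dataset("bench.tsv")
res = ps.StabilityModel(ds, spec=ps.EncodingSpec(11, ("Co", "No"))).fit()
print(res.summary())
pred = res.predict(ds[0])          # Prediction(direction, confidence, value)
res.plot_roc()                     # cross-validated ROC curve
```

Mutation TSV format (tab-separated; `sequence` may instead come from a
companion FASTA keyed by `protein_id`):

```text
protein_id  position  wt  mut  ph   ddg   label     sequence
P1          56        G   S    7.0  -1.2  negative  MSV...
P1          30        A   V    6.5   0.4  positive  MSV...
P2          12        L   P    7.4  -2.1  negative  MKT...
P2          90        D   E    5.0   0.0  positive  MKT...
P3          7         K   R    8.0   1.1  positive  MAE...
```

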