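# qmsdr — quantitative mutation scoring for drug response prediction

Most multi-gene models of cancer drug response reduce each gene to a
binary mutated/unmutated flag, treating a BRAF V600E exactly like a
silent passenger variant in the same gene. `qmsdr` implements the
alternative: encode every somatic mutation by continuous variant-effect
scores — CHASMplus (driver likelihood), VEST4 (functional impact) and
CADD (deleteriousness), all on a common [0, 1) scale — and let a
neural network learn which score patterns predict how a tumor responds
to a drug. It is written for computational biologists who work with
cell-line pharmacogenomic screens (mutation MAFs, annotator score
tables, dose-response summaries) and want to compare mutation
representations, train per-drug response models, and transfer them to
patient cohorts.

## The model

A tumor *t* is a feature matrix X_t of shape (genes × channels): per
gene, either a 0/1 flag (binary), one algorithm's score (single-QMS),
or all three scores plus a binary "not scored" channel (multi-QMS).
Mutated genes carry the **maximum** score over their mutations, per
channel; unmutated genes are zero. A feed-forward network F predicts
the area under the dose-response curve, ȳ_t = F(X_t), where AUDRC = 0
means total cell death and 1 means no effect. F has six layers of
702·x, 512, 512, 2048, 36 and 4 neurons (x = channels per gene); layer
1 is **partitioned by gene** — a block-diagonal linear map giving each
gene a private x-neuron embedding. Every layer applies

    T(x) = Batchnorm(tanh(Linear(Dropout(x))))

and a final affine map emits ȳ. Training minimises
O = MSE(y, ȳ) + λ‖W‖² with AdamW (batch 32, lr₀ = 0.014 reduced 80%
on validation plateaus, early stop after 20 epochs without ≥ 1e-4
improvement). Forward and backward passes are implemented directly in
numpy; input gradients G_f = ∂ȳ/∂f are exact, and their ℓ2 norms over
held-out samples (averaged across cross-validation models) rank
feature and gene importance.

Evaluation uses repeated 70/15/15 train/validation/test splits with
pooled held-out predictions (Pearson r, Fisher r-to-z model
comparison, precision-recall against single-residue biomarkers), and
clinical transfer labels patients as responders when the ensemble
prediction falls in the bottom 20th percentile of measured cell-line
AUDRC (scored by F1 against RECIST, and C-index / Cox hazard ratio
against overall survival).

A fully synthetic data generator emulates every input — per-gene
mutation tables, correlated multi-algorithm scores with missingness,
planted threshold drivers whose high-impact mutations lower AUDRC, and
patient cohorts — so the entire pipeline runs and is tested with no
external data.

## Worked example

`examples/02_train_and_evaluate.py` generates a 400-line, 40-gene
synthetic cohort with a planted threshold driver and races the two
encodings through nested cross-validation:

```
pooled test Pearson r, multi-QMS : 0.521 (n=227)
pooled test Pearson r, binary    : 0.241 (n=227)
difference                       : 0.280
Fisher r-to-z                    : z=3.51, p=4.41e-04
```

Only high-impact driver mutations confer sensitivity in this cohort,
so the binary flag — which cannot tell a hotspot from a passenger in
the same gene — explains far less of the held-out response than the
score channels; the Fisher test says the gap is not chance.
`examples/03_interpret_model.py` then shows the planted driver ranked
first by gradient importance, and `examples/04_clinical_transfer.py`
transfers cell-line models to a synthetic patient cohort:

```
RECIST cohort: 26/150 predicted responders, F1 vs PR = 0.577
survival cohort: C-index = 0.565, hazard ratio (responder) = 0.51
```

Patients the models call sensitive respond more often and live longer.

## Layout

```
src/qmsdr/
  io.py          mutation/score/response/panel readers and writers
  features.py    binary / single-QMS / multi-QMS / marker encodings, entropy
  network.py     the gene-partitioned network, AdamW, schedules (numpy)
  evaluate.py    split plans, nested CV, statistics, clinical transfer
  interpret.py   gradient importances and Sankey export
  simulate.py    synthetic cohort and clinical-cohort generators
  benchmarks.py  canned cohort-level benchmark runs
  cli.py         thin click CLI (`qms`)
examples/        narrative scripts, one per capability
docs/methods.md  modelling and design notes
```
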