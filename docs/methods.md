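# Methods notes

This note records the modelling choices behind `qmsdr`, the parameters
that matter, and what the synthetic cohorts do and do not establish.

## Feature encodings

A sample is a `genes × channels` matrix in [0, 1]. Channel rules:

* **Score channels.** Per gene and algorithm, the value is the maximum
  score over the gene's mutations; the maximum is taken independently
  per channel (not the channel vector of a single argmax mutation),
  the conservative reading when several mutations are present. A
  mutation missing one algorithm's score contributes 0 to that channel
  only.
* **"Not scored" channel.** Fires (value 1) only when the gene carries
  at least one mutation that *no* configured algorithm scored. A
  partially scored mutation does not fire it. This keeps the flag a
  pure missingness indicator rather than a second mutation-status flag.
* **CADD rescaling.** Raw CADD-class values in [0, 99] are divided by
  100, so the maximum raw value 99 maps to exactly 0.99 and all
  channels share the unit scale. The channel order is fixed as
  (CHASMplus, VEST4, CADD, not_scored).
* **Marker features** parse `p.V600E` / `V600E`-style notation; any
  substitution away from the reference amino acid at the marker
  residue, including nonsense, counts as marker-positive; unparseable
  protein changes are counted and treated as non-marker.
* **Entropy.** Representation entropy uses 20 equal-width bins per
  channel on [0, 1] by default and the joint distribution across
  channels, so adding channels can only add information. The binning
  is fixed to make the statistic reproducible.

## The response network

Architecture and training follow the description in the README: six
transfer layers T(x) = Batchnorm(tanh(Linear(Dropout(x)))), a
gene-partitioned first layer, a plain affine output head, and the
objective MSE + λ‖W‖².

Implementation choices, in the order they matter:

* **Block storage of layer 1.** The gene-partitioned layer is stored
  as `n_genes` independent `x × x` blocks rather than a masked dense
  matrix. The contract (each gene's channels feed only its own
  neurons) is identical and is verified structurally in the tests;
  block storage keeps the optimiser from carrying millions of
  permanently-zero entries. `dense_weight()` materialises the
  equivalent block-diagonal matrix for inspection.
* **Exact gradients.** Forward/backward are hand-written numpy. The
  backward pass differentiates through batch statistics in training
  mode (full batch-norm backward) and through the frozen running
  statistics in inference mode, for both parameters and inputs; a
  finite-difference oracle in the tests checks every parameter of a
  small model at relative 1e-3.
* **T applied uniformly.** All six layers use the same transfer
  function, including the partitioned layer; the output head has no
  transfer. Batch-norm running statistics use an exponential moving
  average with momentum 0.1 and the conventional unbiased variance.
* **Decoupled weight decay.** During optimisation the ℓ2 penalty is
  realised as AdamW's multiplicative decay on weight matrices only
  (biases and batch-norm parameters are not decayed). For gradient
  verification, `objective_and_grads(include_penalty=True)` computes
  the explicit penalised objective and its exact gradients instead.
* **Head-bias initialisation.** The output bias starts at the
  training-set mean response. Adam's per-step displacement is bounded
  by the learning rate, so from a random bias the optimiser can spend
  a hundred epochs walking the bias onto the response scale (and on
  small cohorts may stop before arriving, leaving every prediction
  biased low); starting from the baseline predictor removes that
  failure mode without touching the architecture.
* **Improvement bookkeeping.** "Validation improvement" for both the
  plateau scheduler and the early stop means a decrease of validation
  MSE by at least ε = 1e-4 relative to the best seen; the scheduler
  multiplies the rate by 0.2 after 10 non-improving epochs, the stop
  fires after 20, and the best-epoch weights (including running
  statistics) are restored. Dropout defaults to p = 0.1; weight decay
  defaults to λ = 1e-4; optimiser moments are (0.9, 0.999). Batches
  with fewer than two samples are skipped because batch statistics are
  undefined there.

### Desk-scale benchmark configuration

The full-panel defaults (702-gene layer sizes, lr₀ = 0.014) describe a
clinical-panel-sized model. The synthetic cohorts used throughout the
tests and examples are ~40–200 genes, and on them two adjustments are
needed (`qmsdr.benchmarks.benchmark_model_config`):

* a narrower hidden stack (64/64/128/36/4) and a gentler initial rate
  (5e-4): at 0.014 the small networks drive tanh units into
  saturation within a few epochs and never recover;
* much stronger decoupled decay (λ = 24): sparse mutation profiles
  make each sample's fingerprint nearly unique, and without strong
  decay the network memorises training responses through
  passenger-gene patterns — the train/validation gap widens and, more
  subtly, gradient importance then spreads over passenger genes
  instead of concentrating on the planted driver. Strong decay prunes
  pathways that receive no consistent gradient signal.

Stopping patience is 40 epochs (vs 20) to give the plateau scheduler
room to act at the lower rate; everything else is unchanged. These are
problem-size choices, not new modelling content.

## Evaluation harness

* "Nested cross-validation" with 70/15/15 fractions is implemented as
  independent seeded Monte-Carlo splits (default 5): disjoint
  exhaustive partitions per repeat, validation used only for stopping,
  test predicted once. A sample tested in several repeats contributes
  the mean of its held-out predictions to the pooled table; pooled
  Pearson r is the primary statistic (per-repeat r is also
  available). With five repeats the pooled pool covers
  1 − 0.85⁵ ≈ 56% of samples, matching the fraction sizes.
* Percentile operations (responder labelling, patient thresholds) use
  inclusive linear interpolation, and boundary comparisons use ≤ on
  the sensitive side, so ties resolve deterministically.
* Precision-recall areas are step-wise sums Σ(R_i − R_{i−1})·P_i (no
  trapezoids); `recall_at_precision` returns the maximum recall among
  thresholds meeting the floor, 0 when none qualifies.
* The concordance index treats its input as a risk score — larger
  predicts shorter survival — so predicted AUDRC can be passed
  directly for drugs whose responders live longer; pairs are
  comparable only when the shorter time ends in an event (lifelines).
  Hazard ratios come from a univariate Cox fit on the responder flag.
* The shuffled-response control permutes the response vector across
  samples with a stated seed and reruns the full CV. Note the null
  distribution of the pooled r is wider than 1/√n: predictions of
  samples sharing mutated genes are correlated, reducing the
  effective sample size.

## Synthetic cohorts

The generator targets structural, not distributional, fidelity: it
reproduces the features the method's claims depend on, with no attempt
to match any real screen's marginals.

* **Mechanism.** Each mutation carries a latent impact u ∈ [0, 1);
  drug response is 1 − Σ effects·1[max gene impact ≥ τ] + noise,
  clipped at 0, with τ = 0.8, one strong driver (effect 0.5) and
  three weak modifiers. Scoring algorithms observe u through additive
  Gaussian noise (sd 0.05/0.08/0.12) with per-algorithm missingness
  (8/5/10%) and a 10% fully-unscored rate (matching the ~89% scored
  fraction typical of annotator output).
* **Impact mixtures.** Passengers draw u from Beta(1, 5). Driver-gene
  mutations are an even (0.5/0.5) mixture of hotspot draws from
  Beta(8, 2) and the passenger distribution. The even weight is
  deliberate: the generator's purpose is a cohort in which the binary
  mutated/unmutated flag *cannot* separate sub-threshold from
  supra-threshold driver mutations, and when hotspots dominate the
  mixture the binary flag becomes a near-proxy for the threshold and
  the representations no longer differ by construction.
* **Mutation rates.** Passenger genes mutate at 5–15% per sample,
  reflecting that clinical panel genes are selected for recurrent
  mutation; the driver sits at 35% (an enriched, indication-like
  cohort). Very low rates would make each profile nearly unique,
  which both invites memorisation and starves the batch-norm running
  variance of rarely-mutated genes (inflating their inference-mode
  input gradients).
* **Two-driver cohort** (`two_driver_config`): two drivers of similar
  effect, each acting through its own hotspot residue, with a sharp
  hotspot impact distribution (Beta(25, 2), essentially always above
  τ). This mirrors activating-hotspot biology — marker-residue
  mutations specifically elicit sensitivity — so the single-residue
  marker of driver 1 is high-precision but blind to driver 2, which
  is exactly the situation in which a score-based model can extend
  recall at matched precision.
* **Clinical cohorts** share the mutation/score process (fresh
  substreams). RECIST: true responders (noiseless response below
  1 − effect/2) receive PR with probability 0.85, others 0.10, and
  non-PR patients split evenly between SD and PD. Survival: months
  are exponential with mean 24 for true responders and 8 otherwise,
  with independent censoring (rate 0.25).
* **Reproducibility.** One seed spawns named substreams (rates,
  mutations, impacts, scores, responses, cohort), so adding a
  downstream stage never perturbs earlier draws, and a config
  reproduces its cohort exactly.

What passing tests show: that the pipeline recovers planted structure
under its own generative assumptions — threshold mechanisms, additive
effects, independent genes. What they do not show: performance on real
screens, where genes co-mutate, effects interact, dose-response
summaries are themselves fitted quantities, and variant scores are
deterministic per variant rather than noisy observations of a latent
impact.

## Problem sizes

The cohort-level tests run the default synthetic cohort (1200 samples,
200 genes, seed 7) through two full 5-repeat CV runs plus a shuffled
control, and the two-driver cohort through one; with the benchmark
configuration each model fits in roughly 5–15 seconds, and the whole
suite completes in a few minutes on one core. Examples use 400–600
samples and 40 genes as their cohort size.

## Known limitations

* Inference-mode input gradients are scaled by 1/√(running variance)
  per layer-1 neuron, so genes that rarely vary receive inflated
  gradients; importance rankings are reliable only when the model fits
  well and gene mutation rates are not vanishingly small (see the
  weight-decay discussion above).
* One model per drug; no multi-drug joint training, no structural
  variants or fusions, no transcript-level annotation, and no
  re-implementation of the scoring algorithms themselves — score
  tables are consumed as input.
* The marker parser handles single-residue substitution notation only;
  complex HGVS-p descriptions (delins, extensions) are counted as
  unparseable and treated as non-marker.
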