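# Methods

## The classification problem

Protein glycation — the nonenzymatic attachment of sugars and sugar-derived
carbonyls such as methylglyoxal to amino groups — targets lysine side
chains, and no sequence motif reliably marks susceptible sites.  The working
hypothesis behind this package is that the *physicochemical microenvironment*
of a lysine carries the signal: the package therefore encodes each candidate
site as a 31-residue window (15 flanking residues per side, lysine fixed at
position 16) in which every residue letter is replaced by the numeric value
of a physicochemical scale, and trains a small recurrent classifier on those
numeric sequences.

## Property scales

Eight per-residue scales are built in:

| id   | meaning                                   | units         | source of defaults |
|------|-------------------------------------------|---------------|--------------------|
| SoA  | sequence-order code                       | ordinal 1–20  | alphabetical one-letter order |
| Hyd  | hydropathy                                | dimensionless | Kyte–Doolittle |
| Mass | average residue mass                      | Da            | standard residue masses |
| Hyp  | hydrophobicity                            | dimensionless | Fauchère–Pliška octanol π |
| Pol  | polarizability                            | dimensionless | Charton–Charton |
| vdW  | normalized van der Waals volume           | dimensionless | Fauchère et al. |
| ToA  | side-chain torsion (χ) angle count        | count         | standard rotamer conventions |
| IEP  | isoelectric point                         | pH            | free amino-acid pI |

Two of these are deliberate, documented stand-ins where the literature does
not pin a single canonical choice: SoA (there is no standard numeric
"sequence structure" scale; an ordinal code preserves identity information
only) and ToA (several dihedral-preference scales exist; the χ-angle count is
a simple, defensible one).  Both — indeed all eight — can be replaced from a
TSV file via `load_property_table_file`, which makes scale fidelity a
one-file swap rather than a code change.

Raw scales differ by orders of magnitude (residue masses near 100 Da vs.
polarizabilities near 0.1), so each property is z-scored before entering the
network.  The statistics are fitted on the **training split only** (means
and population standard deviations over all non-pad residue positions) and
frozen; validation and test windows are encoded with the training statistics,
so no information can leak backwards.  The padding symbol `X` (used when a
window overhangs a protein terminus) encodes as 0 after standardization —
the population center, i.e. a neutral value.  Ambiguity codes (B, Z, J, U,
O) are rejected, never imputed.

## Input layouts (the three cases)

* **Case 1** — one property per model: a 31×2 matrix whose two columns are
  identical copies of the property's standardized column.  The duplication
  is implemented literally, so cases 1 and 2 share the same input width and
  parameter count and their results are architecturally comparable.
* **Case 2** — one model per unordered property pair: 31×2, column 1 from
  the first property, column 2 from the second.  Eight properties give
  C(8,2) = 28 subcases.
* **Case 3** — all eight properties at once: 31×8, columns in the fixed
  canonical order SoA, Hyd, Mass, Hyp, Pol, vdW, ToA, IEP.

Rows are fed N-terminal → C-terminal (a convention; nothing in the data
dictates an orientation).

## Network and training protocol

The classifier is a fixed stack: LSTM(64, tanh) → dropout → LSTM(32, tanh)
→ dropout → Dense(16, ReLU) → dropout → Dense(2, softmax).  The two output
units give the probability of glycation and non-glycation (summing to 1);
the predicted label is the more probable class, with exact ties resolved to
"nonglycated" (a documented convention — a tie carries no evidence for
modification).

Training minimizes sparse categorical cross-entropy with Adam (learning rate
1e-3, the optimizer's canonical default) at batch size 64, with early
stopping: if validation accuracy has not improved for 20 consecutive epochs
training stops, and the weights of the best epoch (earliest on ties) are
restored.  `max_epochs` defaults to 200 so that patience, not the cap,
terminates training.

Hyperparameters the protocol fixes only structurally get documented
defaults, all configurable: dropout 0.2 on each of the three dropout layers,
and an L2 penalty (λ = 0.01) on the input kernels of both LSTM layers —
"L2-regularized LSTM units" is read as weight regularization on the layer
kernels, and both layers share λ.

The network, backpropagation through time and Adam are implemented directly
on numpy float32 arrays inside the package (`_network.py`).  Gate order is
(input, forget, cell, output); kernels are Glorot-uniform, recurrent
matrices orthogonal (sign-fixed QR), forget-gate biases start at 1.  The
implementation is verified against central-difference numerical gradients
in double precision.  Because every stochastic element (initialization,
shuffling, dropout) draws from explicit seeded generators and no threaded
framework is involved, training is bit-reproducible for a given seed on a
given platform — the repeat-to-repeat variability reported by the experiment
runner comes entirely from the seeds, not from hidden nondeterminism.

## Experiment orchestration

Each subcase is trained `repeats` times (default 20) and its test-set
metrics are averaged; dispersion is reported as the sample (n−1) standard
deviation.  Repeat `r` of subcase `s` uses seed `base_seed + 1000·s + r`, so
any single subcase can be reproduced without rerunning the whole sweep.  The
default data split is 4830/1000/1000 (train/validation/test), stratified by
label, drawn deterministically from a seed; 10-fold cross-validation uses
stratified folds whose sizes differ by at most one, carving a stratified 15%
internal validation set out of each fold's training portion for early
stopping.  The cross-validation grid hook ranks candidate configurations by
mean validation *sensitivity* (accuracy breaking ties), reflecting a
protocol that prioritizes recovering true glycation sites.

Properties are ranked by the repeat-mean of a chosen metric (accuracy by
default), ties broken by canonical property order.  Exports (metrics TSV,
per-subcase ROC CSV, provenance JSON with seeds, config, scale statistics
and dataset hashes) are byte-deterministic for identical inputs.

Splits are stratified by label only — there is no per-protein grouping.
Real datasets of this kind are redundancy-reduced upstream (CD-HIT at 30%
identity), which limits but does not eliminate homology between windows;
this is a known caveat, not something the package corrects.

## Metrics

Accuracy, precision, sensitivity, specificity, MCC (from the confusion
matrix with glycated = positive) and trapezoidal AUC over the tie-grouped
ROC staircase.  A metric whose denominator is zero is reported as 0 and
flagged `undefined` rather than raising, keeping repeat averages total while
remaining auditable.  Repeat summaries are means of per-run metrics (not
metrics of pooled predictions); pooling would weight runs by prediction
count and hide run-to-run variance.

## Synthetic data generator

The generator emulates the *structure* of curated glycation datasets —
balanced binary labels on 31-mers with a fixed central K — with residues
drawn i.i.d. from a configurable background (uniform by default).  The
planted signal follows the package's scientific premise: a standardized mean
of one or more property values over the flanking residues (the center K is
constant and carries nothing), passed through a logistic link,
`P(label=1) = σ(β·z)`, with rejection sampling to hit the class balance
exactly.  `generate_separable` is the β → ∞ limit (labels = z above its
median), giving data a threshold rule classifies perfectly — a clean
capacity oracle for the network.  `generate_null` (β = 0) gives
label-independent sequences for calibration.

What the generator does **not** emulate: real proteome residue composition,
homology/clustering structure, mass-spectrometry detection bias, or any
nonlinear or position-specific glycation chemistry.  Passing the planted-
recovery tests therefore shows the pipeline can detect and attribute a
property-linked signal when one exists; it does not certify any particular
accuracy on real proteomes.

## Problem sizes used by the test suite

The statistical tests run at sizes chosen to make their assertions stable:

* Null calibration: 50 simulations of n = 10,000 balanced labels; the mean
  MCC of a coin-flip classifier is asserted within ±0.02 of 0, and random
  scores give AUC 0.5 ± 0.02.
* Planted recovery: β = 3 on IEP, n = 4000 (split 2800/600/600), 10
  independent replicates of the single-property sweep at 3 repeats per
  subcase.  The sweep uses the full architecture trained for 3 epochs at
  batch 256 — a reduced-length screening protocol; with β = 3 the planted
  property separates from the others within the first epochs, and the
  Bayes accuracy of the generative model (~0.81) bounds what any training
  length could reach.  IEP must rank first in at least 8 of 10 replicates
  with mean accuracy ≥ 0.75, and on null data every subcase must stay in
  [0.45, 0.55].
* Training sanity: the separable set (n = 2000, split 1400/300/300) trained
  under the full protocol (batch 64, patience 20, cap 200) must exceed 0.9
  validation accuracy and stop by patience, not by the cap.

## Known limitations

* The two stand-in scales (SoA, ToA) are placeholders for choices the
  literature leaves open; rankings that hinge on them should be read with
  that in mind.
* Benchmarks on real, externally curated glycation folds (CPLM-derived)
  require downloading those folds; nothing in this repository asserts
  real-data accuracy.
* Mean-of-metrics aggregation and label-only stratification are documented
  conventions; both have pooled/grouped alternatives that are intentionally
  out of scope (pooling available behind `evaluate_predictions` on
  concatenated outputs if needed).
* The numpy training loop is single-threaded by design; wall-clock cost
  grows linearly with repeats × subcases.
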