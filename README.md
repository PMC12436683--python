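# glylstm

**Lysine glycation site classification from physicochemical sequence
encodings, with an LSTM classifier and a property-comparison experiment
protocol.**

Glycation is the nonenzymatic attachment of sugars and reactive carbonyls
(e.g. methylglyoxal) to proteins; lysine side chains are a primary target,
and no sequence motif reliably predicts which lysines get modified.  This
package implements — as a tested, reusable pipeline — the hypothesis that
the *physicochemical microenvironment* of a lysine carries the signal:

1. each candidate site is a 31-residue window with the lysine at position 16
   (terminal overhangs padded with `X`);
2. every residue letter is replaced by the z-scored value of a
   physicochemical amino-acid scale — sequence-order code (SoA), hydropathy
   (Hyd), residue mass (Mass), hydrophobicity (Hyp), polarizability (Pol),
   normalized van der Waals volume (vdW), side-chain torsion-angle count
   (ToA), isoelectric point (IEP) — giving a 31×k numeric matrix;
3. a stacked-LSTM classifier — LSTM(64, tanh, L2) → dropout → LSTM(32) →
   dropout → Dense(16, ReLU) → dropout → softmax(2) — is trained with Adam
   (batch 64, sparse categorical cross-entropy, early stopping on validation
   accuracy with patience 20, best-epoch weights restored);
4. three comparative designs quantify which properties matter: **case 1**
   (each property alone, 31×2 with a duplicated column), **case 2** (all 28
   unordered property pairs, 31×2) and **case 3** (all eight properties,
   31×8).  Each subcase is trained repeatedly (default 20 repeats) and
   evaluated on a held-out test set by accuracy, precision, sensitivity,
   specificity, MCC and ROC/AUC; properties are ranked by repeat-mean
   metric.

The network, backpropagation through time and Adam live inside the package
(pure numpy), so runs are bit-reproducible from a single integer seed.
A synthetic-data module generates balanced 31-mer datasets with a
controllable property-linked signal (logistic link on the flank-mean of a
chosen scale), so the whole pipeline is testable without any downloads.
See `docs/methods.md` for the full model description and design choices.

## Worked example

Simulate a dataset of 2000 windows whose glycation labels depend on the
flanking isoelectric point (effect size β = 3), then compare three single
properties (case 1, 3 repeats each, short screening protocol):

```
glylstm simulate -c sim.yaml -o windows.tsv
glylstm run --case 1 --data windows.tsv -c run.yaml -o case1 \
    --properties IEP --properties Mass --properties Hyd
```

with `sim.yaml`:

```yaml
n: 2000
seed: 7
mode: planted
planted_properties: [IEP]
beta: 3.0
```

and `run.yaml`:

```yaml
seed: 0
repeats: 3
split_sizes: [1400, 300, 300]
model: {batch_size: 256, max_epochs: 3, patience: 3}
```

The run prints the property ranking and writes `case1/case1_metrics.tsv`:

```
ranking (by mean accuracy): IEP, Mass, Hyd

subcase  accuracy_mean  accuracy_sd   ...  mcc_mean   mcc_sd
IEP      0.797778       0.001925      ...  0.596430   0.003280
Mass     0.540000       0.018559      ...  0.084260   0.036326
Hyd      0.522222       0.013472      ...  0.045383   0.027636
```

The planted property (IEP) is recovered decisively: its test accuracy
(~0.80, close to the generative model's Bayes accuracy of ~0.81) and MCC
(~0.60) dominate the unplanted scales, which sit near chance with MCC close
to 0.  Per-subcase ROC curves, a provenance JSON (seeds, configuration,
scale statistics, dataset hashes) and the full result JSON are written
alongside the table; `glylstm cv` runs stratified 10-fold cross-validation,
and `glylstm predict` scores every lysine window of a protein FASTA with a
saved model.

The same pipeline is exposed as a library, including scikit-learn
estimators:

```python
from glylstm import PeptideEncoder, LSTMClassifier, CaseSpec

enc = PeptideEncoder(case_spec=CaseSpec.single("IEP"))
X = enc.fit_transform(train_records)          # (n, 31, 2), stats frozen on train
clf = LSTMClassifier(seed=0).fit(X, y)
proba = clf.predict_proba(enc.transform(test_records))
```

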