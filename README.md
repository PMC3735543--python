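# ervpredict

Predicting whether an intronic endogenous retrovirus (ERV) insertion
disrupts transcription of its host gene.

## Scientific problem

Mouse ERVs of the IAP and ETn/MusD families are active mutagens: an element
that lands inside an intron can derail transcription of the enclosing gene
(aberrant splicing, premature polyadenylation) — or be silently tolerated.
Whether a given insertion is disruptive turns out to be largely predictable
from four properties of the insertion site:

1. **relative orientation** of the ERV with respect to the gene
   (sense insertions are far more often disruptive),
2. **ERV family** (IAP vs ETn/MusD),
3. **size of the enclosing intron** (disruptive insertions favor small
   introns),
4. **distance from the insertion to the nearest exon** (disruptive
   insertions sit close to exons).

`ervpredict` implements this prediction pipeline end to end: deriving the
four factors from genomic annotation (GTF gene models + BED insertions),
encoding them (log-compressed lengths mapped to [0, 1]), training a
consolidated ensemble of small neural networks, evaluating it, scoring new
insertions, and mapping the model's behavior over the whole input space.

## Model

The classifier is a 4–3–1 multilayer perceptron (logistic activations,
19 parameters) trained with full-batch back-propagation (iRprop− by
default). Robustness comes from an ensemble built by stratified 3-fold
cross-validation × 10 random permutations × 100 random reinitializations
(3000 networks by default); the predicted disruption likelihood is the mean
of the member outputs. Cross-validated evaluation scores each held-out case
only with networks that never trained on it. See
[docs/methods.md](docs/methods.md) for the full description.

The package ships no real genomic data: `ervpredict.synthetic_fixtures`
generates structurally realistic synthetic tables (class-conditional
log-normal lengths, sense-enriched positives, a geometric
distance ≤ intron/2 constraint) so the whole pipeline runs self-contained.

## Tests

```bash
python -m pytest -q tests/
```

## Worked example

A reduced run (2 permutations × 3 folds × 10 reinitializations = 60
networks) on a synthetic table of 33 positives and 117 negatives:

```python
from ervpredict import (SynthConfig, TrainConfig, generate_training_like, encode_table,
                        plan_from_labels, train_ensemble, consolidate, cv_performance,
                        threshold_report, predict)

records = generate_training_like(SynthConfig(seed=42))
X, t = encode_table(records)
plan = plan_from_labels(t, permutations=2, seed=42)
model = train_ensemble(plan, (X, t), n_reinits=10, cfg=TrainConfig(seed=42))
print(f"trained members: {model.n_members}")

mean_auc, sd_auc, _ = cv_performance(model, plan, (X, t))
print(f"cross-validated AUC: {mean_auc:.3f} +/- {sd_auc:.3f}")

rep = threshold_report(consolidate(model, X), t.astype(int), tau=0.5)
print(f"at threshold 0.5: sensitivity {rep.sensitivity:.1f}%, specificity {rep.specificity:.1f}%")

calls = predict(model, records[:3], tau=0.5)
print(calls[["id", "likelihood", "call"]].to_string(index=False))
```

Output:

```
trained members: 60
cross-validated AUC: 0.944 +/- 0.037
at threshold 0.5: sensitivity 87.9%, specificity 99.1%
     id  likelihood     call
pos0001    0.567151 positive
pos0002    0.158308 negative
pos0003    0.990276 positive
```

The same flow is available from the command line:

```bash
ervpredict synth --out train.tsv --seed 7
ervpredict train --table train.tsv --out model.json --permutations 2 --reinits 10 --seed 7
ervpredict evaluate --table train.tsv --model model.json --out metrics.json
ervpredict predict --table train.tsv --model model.json --out calls.tsv --threshold 0.5
ervpredict simulate --model model.json --outdir grids/ --n-units 100
ervpredict plot --grid grids/grid_IAP_sense.tsv --out iap_sense.png --table train.tsv
```

To derive the four factors from genomic annotation instead of a synthetic
table, start from a GTF of gene models and a BED6 of insertions (name field
`id|family`):

```bash
ervpredict extract-features --bed insertions.bed --gtf genes.gtf --out factors.tsv
```

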