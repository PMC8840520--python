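# confsel

Two-stage sampling-based classification of drug-binding vs non-binding
protein conformations from molecular-descriptor tables under severe class
imbalance.

A conformational ensemble of a drug target contains only a minority of
conformations that ligands actually bind (class 1, "active binding").
Classifiers trained on such tables are biased toward the non-binding
majority (class 0). `confsel` implements a two-stage remedy:

1. **Stage 1** — logistic regression (cross-entropy cost, L2 penalty
   `1/(2C)·‖w‖²`, batch gradient descent with backtracking) fit on the
   original imbalanced training set; it excels at detecting non-binding
   conformations.
2. **Stage 2** — the training set's class balance is *inverted*: class 0 is
   randomly undersampled to the original class-1 count and class 1 is
   SMOTE-oversampled to the original class-0 count (total size preserved).
   A Gaussian naive Bayes or K-nearest-neighbors learner fit on this
   inverted set recovers binding conformations that stage 1 missed.
3. **Decision fusion** — per-sample reconciliation of the two stages on the
   shared test set yields a ledger (TP1/TN1, reconfirmed TP2, new TP2, new
   TN2) and the fused metrics
   `TotalAccuracy = 100·(TP1+TN1+NewTP2+NewTN2)/Ntest`,
   `TPacc = 100·(TP1+NewTP2)/Ntest1`, `TNacc = 100·(TN1+NewTN2)/Ntest0`.

**Caveat:** the fusion ledger credits a sample as correct if *either* stage
classifies it correctly, which requires the true labels to resolve
disagreements. It is an optimistic triage/audit metric (an upper bound),
not a deployable label-free classifier. A label-free union rule
("predict 1 iff either stage predicts 1") is available via
`fuse_label_free` / the `include_label_free` config flag.

All three base learners are implemented from scratch (scikit-learn appears
only as an independent oracle in the tests). Real descriptor tables of this
kind are distribution-restricted, so the package ships a seeded synthetic
generator that emulates their shape: ~3000 rows, 50 continuous features on
heterogeneous scales, imbalance ratios 3:1 or 20:1, tunable class
separation.

## CLI

```bash
# generate a synthetic 3:1 descriptor table (2997 rows, 850 positives)
confsel simulate --preset adora2a-like --seed 1 --out data/adora2a.csv

# run the two-stage pipeline per a YAML config
cat > config.yaml <<EOF
input: data/adora2a.csv
fractions: [0.10, 0.20, 0.30]
seed: 7
lr_c: 5
knn_k: 5
smote_k: 5
learners: [gaussian_nb, knn]
output_dir: runs
EOF
confsel run config.yaml          # writes report_fracXX.json + summary text

# metric arithmetic straight from printed integer counts
confsel metrics --tp 151 --tn 1313 --fn 428 --fp 206
confsel metrics --tp 0 --tn 2001 --fn 96 --fp 3 \
    --new-tp2 93 --new-tn2 0 --ntest1 96 --ntest0 2004
```

Notes: "GB" in some published tables denotes **Gaussian naive Bayes**
(accepted here as the alias `gb` for the `gaussian_nb` learner), not
gradient boosting. Features are z-scored inside LR and KNN by default
(descriptor scales differ by orders of magnitude); naive Bayes is
scale-equivariant and uses raw features.

## Package layout

| module | contents |
| --- | --- |
| `confsel.datasets` | `LabeledDataset`, CSV I/O, seeded `random_split` |
| `confsel.classifiers` | logistic regression, Gaussian NB, KNN (from scratch) |
| `confsel.resampling` | `smote_oversample`, `random_undersample`, `invert_class_balance` |
| `confsel.metrics` | confusion counts, Acc/Se/Sp, ROC/AUC, F1 |
| `confsel.pipeline` | stage runners, fusion ledger, fused metrics, `run_two_stage` |
| `confsel.synth` | seeded imbalanced Gaussian descriptor-table generator |
| `confsel.cli` | `confsel simulate | run | metrics` |

Metric conventions: accuracy is a percent in [0, 100]; sensitivity and
specificity are ratios in [0, 1]; ratios with a zero denominator are
reported as an explicit undefined marker (`None`), never silently 0. All
values are kept at full precision internally — comparisons against
one/two-decimal published tables should use a tolerance of one unit in the
last printed decimal, since such tables mix rounding and truncation.
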