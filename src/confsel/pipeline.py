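"""Two-stage classification pipeline with decision-fusion accounting.

Stage 1 fits logistic regression on the original (imbalanced) training set
to maximize detection of non-binding conformations (class 0).  Stage 2
inverts the class balance of the same training set (undersample class 0,
SMOTE class 1) and fits a minority-oriented learner (Gaussian NB or KNN) to
recover binding conformations (class 1).  The fusion ledger reconciles the
two stages on the shared fixed test set:

- ``reconfirmed_tp2``: true positives found by both stages,
- ``new_tp2``: true positives stage 2 found that stage 1 missed,
- ``new_tn2``: true negatives stage 2 found that stage 1 missed,

from which TotalAccuracy = 100*(TP1+TN1+NewTP2+NewTN2)/Ntest,
TPacc = 100*(TP1+NewTP2)/Ntest1, TNacc = 100*(TN1+NewTN2)/Ntest0.

NOTE: this ledger credits a sample as correctly handled if EITHER stage
classifies it correctly, which requires the true labels to resolve
disagreements.  It is an optimistic triage/audit metric — an upper bound —
not a deployable label-free classifier.  A label-free union rule ("predict 1
iff either stage predicts 1") is available via ``fuse_label_free`` and the
``include_label_free`` config flag.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from confsel.classifiers import (
    KNNConfig,
    fit_gaussian_nb,
    fit_logistic,
    predict_gaussian_nb,
    predict_knn,
    predict_logistic,
)
from confsel.datasets import LabeledDataset, random_split
from confsel.exceptions import ConfigurationError, MetricError
from confsel.metrics import (
    ConfusionCounts,
    class_metrics,
    confusion,
    f1_score,
    roc_auc,
)
from confsel.resampling import SMOTEConfig, invert_class_balance

STAGE2_LEARNERS = ("gaussian_nb", "knn")
#: alias used in some published tables for the Gaussian naive Bayes learner
LEARNER_ALIASES = {"gb": "gaussian_nb", "smote-gb": "gaussian_nb",
                   "smote-knn": "knn"}


@dataclass
class StageResult:
    """Predictions of one stage on the fixed test set."""

    stage: int
    predictions: np.ndarray
    scores: np.ndarray
    counts: ConfusionCounts
    learner: str = "lr"

    def __post_init__(self) -> None:
        self.predictions = np.asarray(self.predictions, dtype=int)
        self.scores = np.asarray(self.scores, dtype=float)
        if self.predictions.shape != self.scores.shape:
            raise ValueError("predictions/scores length mismatch")
        if self.counts.n != self.predictions.size:
            raise ValueError("confusion counts inconsistent with predictions")


@dataclass(frozen=True)
class FusionLedger:
    """Stage-1/stage-2 reconciliation counts over the shared test set."""

    tp1: int
    tn1: int
    fn1: int
    fp1: int
    tp2: int
    tn2: int
    reconfirmed_tp2: int
    new_tp2: int
    new_tn2: int
    n_test: int
    n_test1: int
    n_test0: int

    def __post_init__(self) -> None:
        if self.new_tp2 != self.tp2 - self.reconfirmed_tp2:
            raise ValueError("ledger identity new_tp2 == tp2 - reconfirmed_tp2 violated")
        if self.new_tp2 > self.fn1:
            raise ValueError("new_tp2 exceeds stage-1 false negatives")
        if self.new_tn2 > self.fp1:
            raise ValueError("new_tn2 exceeds stage-1 false positives")
        if self.reconfirmed_tp2 > min(self.tp1, self.tp2):
            raise ValueError("reconfirmed_tp2 exceeds min(tp1, tp2)")
        if self.n_test != self.n_test1 + self.n_test0:
            raise ValueError("n_test != n_test1 + n_test0")


@dataclass(frozen=True)
class FusedMetrics:
    """Fused percentages; ``None`` marks an undefined denominator."""

    total_accuracy: float
    tp_acc: float | None
    tn_acc: float | None


@dataclass
class TwoStageConfig:
    """Configuration of a full two-stage run."""

    fraction: float = 0.30
    seed: int = 0
    lr_C: float = 5.0
    lr_max_iter: int = 2000
    lr_tol: float = 1e-8
    knn_k: int = 5
    smote_k: int = 5
    learners: tuple[str, ...] = STAGE2_LEARNERS
    standardize: bool = True
    include_label_free: bool = False


def run_stage1(
    train: LabeledDataset,
    test: LabeledDataset,
    lr_C: float = 5.0,
    max_iter: int = 2000,
    tol: float = 1e-8,
    standardize: bool = True,
) -> StageResult:
    """Fit LR on the original (imbalanced) training set; predict the test set."""
    model = fit_logistic(
        train, C=lr_C, max_iter=max_iter, tol=tol, standardize=standardize
    )
    proba, pred = predict_logistic(model, test.features)
    return StageResult(
        stage=1,
        predictions=pred,
        scores=proba,
        counts=confusion(test.labels, pred),
        learner="lr",
    )


def run_stage2(
    train: LabeledDataset,
    test: LabeledDataset,
    learner: str,
    smote_config: SMOTEConfig = SMOTEConfig(),
    seed: int = 0,
    knn_config: KNNConfig = KNNConfig(),
) -> StageResult:
    """Invert the training balance, fit the stage-2 learner, predict test.

    ``learner`` is ``"gaussian_nb"`` (alias "gb") or ``"knn"``.  The test
    set must be the same fixed set stage 1 was evaluated on.
    """
    learner = LEARNER_ALIASES.get(learner.lower(), learner.lower())
    if learner not in STAGE2_LEARNERS:
        raise ConfigurationError(
            f"unknown stage-2 learner {learner!r}; expected one of "
            f"{STAGE2_LEARNERS}"
        )
    original_counts = train.class_counts()
    inverted = invert_class_balance(train, smote_config, seed=seed)
    new_counts = inverted.class_counts()
    if original_counts[0] >= original_counts[1]:
        # contract: inversion swaps the per-class counts exactly
        assert new_counts == {0: original_counts[1], 1: original_counts[0]}
    if learner == "gaussian_nb":
        model = fit_gaussian_nb(inverted)
        post, pred = predict_gaussian_nb(model, test.features)
        scores = post[:, 1]
    else:
        scores, pred = predict_knn(inverted, test.features, knn_config)
    return StageResult(
        stage=2,
        predictions=pred,
        scores=scores,
        counts=confusion(test.labels, pred),
        learner=learner,
    )


def fuse(
    stage1: StageResult, stage2: StageResult, y_true
) -> FusionLedger:
    """Per-sample reconciliation of the two stages against true labels."""
    y_true = np.asarray(y_true, dtype=int)
    s1 = stage1.predictions
    s2 = stage2.predictions
    if not (y_true.shape == s1.shape == s2.shape):
        raise MetricError("stages evaluated on differently sized test sets")
    pos = y_true == 1
    neg = ~pos
    reconfirmed = int(np.sum(pos & (s1 == 1) & (s2 == 1)))
    new_tp2 = int(np.sum(pos & (s1 == 0) & (s2 == 1)))
    new_tn2 = int(np.sum(neg & (s1 == 1) & (s2 == 0)))
    c1 = stage1.counts
    c2 = stage2.counts
    return FusionLedger(
        tp1=c1.tp, tn1=c1.tn, fn1=c1.fn, fp1=c1.fp,
        tp2=c2.tp, tn2=c2.tn,
        reconfirmed_tp2=reconfirmed,
        new_tp2=new_tp2,
        new_tn2=new_tn2,
        n_test=y_true.size,
        n_test1=int(pos.sum()),
        n_test0=int(neg.sum()),
    )


def fused_metrics(ledger: FusionLedger) -> FusedMetrics:
    """TotalAccuracy, TPacc, TNacc from the fusion ledger (percents)."""
    if ledger.n_test == 0:
        raise MetricError("empty test set")
    total = 100.0 * (
        ledger.tp1 + ledger.tn1 + ledger.new_tp2 + ledger.new_tn2
    ) / ledger.n_test
    tp_acc = (
        100.0 * (ledger.tp1 + ledger.new_tp2) / ledger.n_test1
        if ledger.n_test1 > 0 else None
    )
    tn_acc = (
        100.0 * (ledger.tn1 + ledger.new_tn2) / ledger.n_test0
        if ledger.n_test0 > 0 else None
    )
    return FusedMetrics(total_accuracy=total, tp_acc=tp_acc, tn_acc=tn_acc)


def fuse_label_free(stage1: StageResult, stage2: StageResult) -> np.ndarray:
    """Union rule: predict 1 iff either stage predicts 1 (no true labels)."""
    if stage1.predictions.shape != stage2.predictions.shape:
        raise MetricError("stages evaluated on differently sized test sets")
    return ((stage1.predictions == 1) | (stage2.predictions == 1)).astype(int)


def _stage_report(result: StageResult, y_true: np.ndarray) -> dict:
    c = result.counts
    m = class_metrics(c)
    roc = roc_auc(y_true, result.scores)
    return {
        "learner": result.learner,
        "counts": {"tp": c.tp, "tn": c.tn, "fp": c.fp, "fn": c.fn},
        "accuracy": m.accuracy,
        "sensitivity": m.sensitivity,
        "specificity": m.specificity,
        "auc": roc.auc,
        "f1": f1_score(c.tp, c.fp, c.fn) if (2 * c.tp + c.fp + c.fn) else None,
    }


def run_two_stage(data: LabeledDataset, config: TwoStageConfig) -> dict:
    """Execute split -> stage 1 -> stage 2(s) -> fusion; return a report.

    Fully reproducible from ``config``: the root seed is split into
    independent child seeds for the train/test split and for each stage-2
    learner's resampling randomness.
    """
    ss = np.random.SeedSequence(config.seed)
    split_seed, *stage2_seeds = [
        int(s.generate_state(1)[0]) for s in ss.spawn(1 + len(config.learners))
    ]
    split = random_split(data, config.fraction, seed=split_seed)
    train, test = split.train, split.test

    stage1 = run_stage1(
        train, test,
        lr_C=config.lr_C, max_iter=config.lr_max_iter, tol=config.lr_tol,
        standardize=config.standardize,
    )
    report: dict = {
        "config": {
            **dataclasses.asdict(config),
            "learners": list(config.learners),
        },
        "seeds": {"root": config.seed, "split": split_seed},
        "split": {
            "n_train": train.n_samples,
            "n_test": test.n_samples,
            "train_class_counts": train.class_counts(),
            "test_class_counts": test.class_counts(),
        },
        "stage1": _stage_report(stage1, test.labels),
        "stage2": {},
        "fusion": {},
    }
    for learner, s2_seed in zip(config.learners, stage2_seeds):
        canonical = LEARNER_ALIASES.get(learner.lower(), learner.lower())
        stage2 = run_stage2(
            train, test, learner,
            smote_config=SMOTEConfig(k=config.smote_k, seed=s2_seed),
            seed=s2_seed,
            knn_config=KNNConfig(k=config.knn_k,
                                 standardize=config.standardize),
        )
        report["seeds"][f"stage2_{canonical}"] = s2_seed
        report["stage2"][canonical] = _stage_report(stage2, test.labels)

        ledger = fuse(stage1, stage2, test.labels)
        fm = fused_metrics(ledger)
        avg_scores = 0.5 * (stage1.scores + stage2.scores)
        fusion_entry = {
            "ledger": dataclasses.asdict(ledger),
            "total_accuracy": fm.total_accuracy,
            "tp_acc": fm.tp_acc,
            "tn_acc": fm.tn_acc,
            # one of several possible fused-score constructions; labeled as such
            "score_average_auc": roc_auc(test.labels, avg_scores).auc,
            "fused_f1_from_ledger": f1_score(
                ledger.tp1 + ledger.new_tp2,
                max(ledger.fp1 - ledger.new_tn2, 0),
                ledger.n_test1 - (ledger.tp1 + ledger.new_tp2),
            ),
        }
        if config.include_label_free:
            union_pred = fuse_label_free(stage1, stage2)
            uc = confusion(test.labels, union_pred)
            um = class_metrics(uc)
            fusion_entry["label_free_union"] = {
                "counts": {"tp": uc.tp, "tn": uc.tn, "fp": uc.fp, "fn": uc.fn},
                "accuracy": um.accuracy,
                "sensitivity": um.sensitivity,
                "specificity": um.specificity,
            }
        report["fusion"][canonical] = fusion_entry
    return report


def format_summary(report: dict) -> str:
    """Plain-text summary table of a run report, for eyeballing."""
    lines = []
    frac = report["config"]["fraction"]
    lines.append(f"training fraction: {frac:.0%}  "
                 f"(train={report['split']['n_train']}, "
                 f"test={report['split']['n_test']})")
    header = f"{'stage/learner':<22}{'TP':>6}{'TN':>6}{'FN':>6}{'FP':>6}" \
             f"{'Acc':>8}{'Se':>7}{'Sp':>7}"
    lines.append(header)
    rows = [("stage1/lr", report["stage1"])]
    rows += [(f"stage2/{k}", v) for k, v in report["stage2"].items()]
    for name, r in rows:
        c = r["counts"]
        se = "n/a" if r["sensitivity"] is None else f"{r['sensitivity']:.3f}"
        sp = "n/a" if r["specificity"] is None else f"{r['specificity']:.3f}"
        lines.append(
            f"{name:<22}{c['tp']:>6}{c['tn']:>6}{c['fn']:>6}{c['fp']:>6}"
            f"{r['accuracy']:>8.1f}{se:>7}{sp:>7}"
        )
    lines.append(f"{'fusion':<22}{'TotalAcc':>10}{'TPacc':>9}{'TNacc':>9}")
    for name, f in report["fusion"].items():
        tp_acc = "n/a" if f["tp_acc"] is None else f"{f['tp_acc']:.1f}"
        tn_acc = "n/a" if f["tn_acc"] is None else f"{f['tn_acc']:.1f}"
        lines.append(
            f"{'lr+smote-' + name:<22}{f['total_accuracy']:>10.1f}"
            f"{tp_acc:>9}{tn_acc:>9}"
        )
    return "\n".join(lines)
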