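"""Subject-aware cross-validation, metrics, ROC curves, feature importance.

Folds partition *subjects*, never windows: grouped 10-fold assigns whole
subjects to folds, and leave-one-subject-out (LOSO) holds out one subject
per fold, so no subject contributes to both training and testing of the
same fold.  Within each fold the training partition is oversampled
(3:1 majority:minority), models are fitted, and test windows predicted;
confusion counts are pooled (micro-averaged) across folds.  ROC curves use
pooled window scores; the hard-voting ensemble carries no score and gets
no ROC.  Feature importance is the normalised mean decrease in Gini
impurity (MDI) of the random-forest member, with inter-tree variability,
averaged across folds.  Undefined metrics (zero denominators) are reported
as missing, never as 0.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import roc_curve

from .labeling import HYPO, NONHYPO, ResampleSpec, oversample_training
from .models import (FittedModel, ModelSpec, SequenceSpec, default_member_specs,
                     majority_vote, predict_window, sequential_classify, train)

log = logging.getLogger(__name__)

ENSEMBLE = "ensemble"


# ---------------------------------------------------------------------------
# fold plans
# ---------------------------------------------------------------------------

@dataclass
class FoldPlan:
    """Per-fold train/test subject sets for a grouped CV scheme."""

    scheme: str
    folds: list[tuple[tuple[str, ...], tuple[str, ...]]]
    seed: int = 0

    def __post_init__(self) -> None:
        for tr, te in self.folds:
            if set(tr) & set(te):
                raise ValueError("a subject appears in both train and test")

    def __len__(self) -> int:
        return len(self.folds)


def make_folds(subjects, scheme: str = "loso", k: int = 10,
               seed: int = 0) -> FoldPlan:
    """Build a subject-level fold plan.

    ``scheme='loso'`` yields one fold per subject; ``'grouped_kfold'``
    shuffles subjects (seeded) and splits them into ``k`` groups.  Raises
    ``ValueError`` with fewer than 2 subjects, or fewer subjects than
    folds.
    """
    uniq = list(dict.fromkeys(subjects))  # order-preserving unique
    if len(uniq) < 2:
        raise ValueError("need at least 2 subjects for subject-aware CV")
    if scheme == "loso":
        folds = [(tuple(s for s in uniq if s != sid), (sid,)) for sid in uniq]
        return FoldPlan("loso", folds, seed)
    if scheme == "grouped_kfold":
        if len(uniq) < k:
            raise ValueError(f"{len(uniq)} subjects cannot fill {k} folds")
        order = list(np.array(uniq, dtype=object)[
            np.random.default_rng(seed).permutation(len(uniq))])
        groups = np.array_split(np.array(order, dtype=object), k)
        folds = []
        for g in groups:
            te = tuple(str(s) for s in g)
            tr = tuple(s for s in uniq if s not in te)
            folds.append((tr, te))
        return FoldPlan("grouped_kfold", folds, seed)
    raise ValueError(f"unknown CV scheme {scheme!r}")


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

@dataclass
class MetricsReport:
    """Confusion counts and the derived proportions (hypo = positive)."""

    tp: int = 0
    fp: int = 0
    tn: int = 0
    fn: int = 0

    def add(self, y_true: np.ndarray, y_pred: np.ndarray) -> None:
        y_true = np.asarray(y_true)
        y_pred = np.asarray(y_pred)
        self.tp += int(((y_true == HYPO) & (y_pred == HYPO)).sum())
        self.fp += int(((y_true == NONHYPO) & (y_pred == HYPO)).sum())
        self.tn += int(((y_true == NONHYPO) & (y_pred == NONHYPO)).sum())
        self.fn += int(((y_true == HYPO) & (y_pred == NONHYPO)).sum())

    @staticmethod
    def _ratio(num: int, den: int) -> float | None:
        return num / den if den > 0 else None

    @property
    def precision(self) -> float | None:
        return self._ratio(self.tp, self.tp + self.fp)

    @property
    def recall(self) -> float | None:
        return self._ratio(self.tp, self.tp + self.fn)

    @property
    def specificity(self) -> float | None:
        return self._ratio(self.tn, self.tn + self.fp)

    @property
    def f1(self) -> float | None:
        p, r = self.precision, self.recall
        if p is None or r is None or p + r == 0:
            return None
        return 2 * p * r / (p + r)

    @property
    def accuracy(self) -> float | None:
        return self._ratio(self.tp + self.tn, self.total)

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    def as_dict(self) -> dict:
        return {"tp": self.tp, "fp": self.fp, "tn": self.tn, "fn": self.fn,
                "precision": self.precision, "recall": self.recall,
                "specificity": self.specificity, "f1": self.f1,
                "accuracy": self.accuracy}


@dataclass
class RocCurve:
    """ROC curve from pooled window scores, AUROC by the trapezoid rule."""

    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auroc: float


def roc_from_scores(y_true: np.ndarray, scores: np.ndarray) -> RocCurve:
    fpr, tpr, thr = roc_curve(y_true, scores, pos_label=HYPO)
    return RocCurve(fpr, tpr, thr, float(np.trapezoid(tpr, fpr)))


def concordance_auroc(y_true: np.ndarray, scores: np.ndarray) -> float:
    """Rank-statistic AUROC: P(score_pos > score_neg) + 0.5 P(tie).

    Independent of the trapezoid construction; used as a cross-check.
    """
    y_true = np.asarray(y_true)
    pos = np.sort(np.asarray(scores)[y_true == HYPO])
    neg = np.sort(np.asarray(scores)[y_true == NONHYPO])
    if pos.size == 0 or neg.size == 0:
        raise ValueError("need both classes for AUROC")
    # count concordant pairs via searchsorted on the sorted negatives
    greater = np.searchsorted(neg, pos, side="left").sum()
    ties = (np.searchsorted(neg, pos, side="right")
            - np.searchsorted(neg, pos, side="left")).sum()
    return float((greater + 0.5 * ties) / (pos.size * neg.size))


# ---------------------------------------------------------------------------
# feature importance
# ---------------------------------------------------------------------------

def mdi_importance(fitted: FittedModel,
                   feature_names: list[str] | None = None) -> pd.DataFrame:
    """Normalised mean-decrease-in-impurity importance with inter-tree SD.

    Returns a frame indexed by feature, columns ``mdi`` (summing to 1) and
    ``mdi_sd`` (SD across trees), sorted descending.  Raises ``TypeError``
    for non-forest models.
    """
    forest = fitted.forest  # TypeError if not a random forest
    names = feature_names or fitted.feature_names
    mdi = forest.feature_importances_
    per_tree = np.array([t.feature_importances_ for t in forest.estimators_])
    df = pd.DataFrame({"mdi": mdi, "mdi_sd": per_tree.std(axis=0)}, index=names)
    return df.sort_values("mdi", ascending=False)


# ---------------------------------------------------------------------------
# cross-validated run
# ---------------------------------------------------------------------------

@dataclass
class CvReport:
    """Pooled and per-fold results of one cross-validated pipeline run."""

    scheme: str
    window_metrics: dict[str, MetricsReport]
    sequence_metrics: dict[str, MetricsReport]
    roc: dict[str, RocCurve]
    importance: pd.DataFrame | None
    fold_window_metrics: list[dict[str, MetricsReport]] = field(default_factory=list)
    n_windows: int = 0
    n_sequences: int = 0

    def summary(self) -> pd.DataFrame:
        rows = {}
        for name, m in self.window_metrics.items():
            row = m.as_dict()
            row["auroc"] = self.roc[name].auroc if name in self.roc else None
            rows[name] = row
        return pd.DataFrame(rows).T


def run_cv(X: pd.DataFrame, y: np.ndarray, subjects: np.ndarray,
           plan: FoldPlan,
           specs: list[ModelSpec] | None = None,
           threshold: float = 0.5,
           oversample_ratio: float | None = 3.0,
           sequence_ids: np.ndarray | None = None,
           seq_spec: SequenceSpec | None = None,
           seed: int = 0) -> CvReport:
    """Run the full per-fold pipeline and pool results.

    Per fold: oversample the training partition only, fit every member,
    predict the held-out subjects' windows, majority-vote the ensemble,
    and aggregate window predictions into sequence decisions for every
    complete test sequence block.  A runtime leakage guard asserts train
    and test subjects are disjoint in every fold.
    """
    specs = specs if specs is not None else default_member_specs(seed)
    seq_spec = seq_spec or SequenceSpec()
    y = np.asarray(y)
    subjects = np.asarray(subjects)
    names = [s.kind for s in specs]
    if len(set(names)) != len(names):
        raise ValueError("duplicate member kinds in the ensemble")

    window_metrics = {n: MetricsReport() for n in names + [ENSEMBLE]}
    sequence_metrics = {n: MetricsReport() for n in names + [ENSEMBLE]}
    pooled_scores: dict[str, list[np.ndarray]] = {n: [] for n in names}
    pooled_truth: list[np.ndarray] = []
    fold_window_metrics: list[dict[str, MetricsReport]] = []
    importances: list[pd.DataFrame] = []
    n_sequences = 0

    for fold_i, (train_subj, test_subj) in enumerate(plan.folds):
        train_set, test_set = set(train_subj), set(test_subj)
        assert not (train_set & test_set), "subject leakage between partitions"
        tr = np.isin(subjects, list(train_set))
        te = np.isin(subjects, list(test_set))
        if not te.any() or not tr.any():
            log.warning("fold %d has an empty partition; skipped", fold_i)
            continue
        Xtr, ytr = X[tr], y[tr]
        Xte, yte = X[te], y[te]
        if np.unique(ytr).size < 2:
            log.warning("fold %d training data single-class; skipped", fold_i)
            continue

        if oversample_ratio is not None:
            rng = np.random.default_rng(np.random.SeedSequence([seed, fold_i]))
            keep = oversample_training(
                ytr, spec=ResampleSpec(oversample_ratio, seed), rng=rng)
            Xtr, ytr = Xtr.iloc[keep], ytr[keep]

        votes = np.empty((int(te.sum()), len(specs)), dtype=int)
        fold_report: dict[str, MetricsReport] = {}
        for j, spec in enumerate(specs):
            fitted = train(spec, Xtr, ytr)
            pred, score = predict_window(fitted, Xte, threshold)
            votes[:, j] = pred
            window_metrics[spec.kind].add(yte, pred)
            fm = MetricsReport(); fm.add(yte, pred)
            fold_report[spec.kind] = fm
            pooled_scores[spec.kind].append(score)
            if spec.kind == "random_forest":
                importances.append(mdi_importance(fitted))
        pooled_truth.append(yte)

        ens_pred = majority_vote(votes)
        window_metrics[ENSEMBLE].add(yte, ens_pred)
        fm = MetricsReport(); fm.add(yte, ens_pred)
        fold_report[ENSEMBLE] = fm
        fold_window_metrics.append(fold_report)

        if sequence_ids is not None:
            n_sequences += _add_sequence_metrics(
                sequence_ids, te, y, names, votes, ens_pred, seq_spec,
                sequence_metrics)

    y_pool = np.concatenate(pooled_truth) if pooled_truth else np.empty(0, int)
    roc: dict[str, RocCurve] = {}
    for n in names:
        if pooled_scores[n] and np.unique(y_pool).size == 2:
            roc[n] = roc_from_scores(y_pool, np.concatenate(pooled_scores[n]))

    importance = None
    if importances:
        mdi = pd.concat([d["mdi"] for d in importances], axis=1).mean(axis=1)
        sd = pd.concat([d["mdi_sd"] for d in importances], axis=1).mean(axis=1)
        importance = (pd.DataFrame({"mdi": mdi, "mdi_sd": sd})
                      .sort_values("mdi", ascending=False))

    return CvReport(plan.scheme, window_metrics, sequence_metrics, roc,
                    importance, fold_window_metrics,
                    n_windows=int(y_pool.size), n_sequences=n_sequences)


def _add_sequence_metrics(sequence_ids, te, y, names, votes, ens_pred,
                          seq_spec, sequence_metrics) -> int:
    """Aggregate test-fold window predictions per sequence block."""
    te_idx = np.flatnonzero(te)
    pos_in_fold = {int(g): k for k, g in enumerate(te_idx)}
    seq_te = sequence_ids[te_idx]
    count = 0
    for sid in np.unique(seq_te):
        if sid < 0:
            continue
        members = np.flatnonzero(sequence_ids == sid)
        if members.size != seq_spec.seq_len or not te[members].all():
            continue
        rows = np.array([pos_in_fold[int(g)] for g in members])
        truth = int(y[members[0]])
        for j, n in enumerate(names):
            sequence_metrics[n].add([truth],
                                    [sequential_classify(votes[rows, j], seq_spec)])
        sequence_metrics[ENSEMBLE].add(
            [truth], [sequential_classify(ens_pred[rows], seq_spec)])
        count += 1
    return count


# ---------------------------------------------------------------------------
# report writers
# ---------------------------------------------------------------------------

def write_report(report: CvReport, outdir) -> None:
    """Write metrics JSON/CSV, ROC point CSVs and the importance ranking."""
    from pathlib import Path
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    payload = {
        "scheme": report.scheme,
        "n_windows": report.n_windows,
        "n_sequences": report.n_sequences,
        "window_metrics": {k: v.as_dict() for k, v in report.window_metrics.items()},
        "sequence_metrics": {k: v.as_dict() for k, v in report.sequence_metrics.items()},
        "auroc": {k: v.auroc for k, v in report.roc.items()},
    }
    with open(outdir / "metrics.json", "w") as fh:
        json.dump(payload, fh, indent=1)
    report.summary().to_csv(outdir / "metrics.csv")
    for name, curve in report.roc.items():
        pd.DataFrame({"fpr": curve.fpr, "tpr": curve.tpr,
                      "threshold": curve.thresholds}).to_csv(
            outdir / f"roc_{name}.csv", index=False)
    if report.importance is not None:
        report.importance.to_csv(outdir / "importance.csv")
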