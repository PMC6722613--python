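"""ROC/AUC evaluation: overall, per frequency stratum, and per
inclusion-level bin, aggregated over cross-validation folds.

AUC is the Mann-Whitney pair statistic (probability that a random positive
outscores a random negative, ties counted one half), computed with the
mid-rank formula.  Strata restrict the *alternative* class only: the full
constitutive negative set is reused in every stratum and bin, mirroring how
the classifiers are asked to separate e.g. highly-included cassette exons
from all constitutive exons.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .models import POSITIVE_CLASS

__all__ = [
    "UndefinedAUCError",
    "EvalReport",
    "roc_auc",
    "roc_curve_points",
    "aggregate_folds",
    "format_auc",
    "stratified_report",
    "inclusion_bin_auc",
]

DSC_CLASSES = ("CON", "ES", "ALT3", "ALT5")


class UndefinedAUCError(ValueError):
    """AUC is undefined when only one class is present."""


def roc_auc(scores, labels) -> float:
    """Mann-Whitney AUC with mid-rank tie handling.

    Equals the fraction of (positive, negative) pairs where the positive
    scores higher, counting ties as half a pair.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have equal length")
    pos = labels == 1
    n_pos = int(pos.sum())
    n_neg = int(len(labels) - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise UndefinedAUCError("both classes must be present to compute AUC")
    ranks = rankdata(scores)  # mid-ranks
    u = ranks[pos].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def roc_curve_points(scores, labels) -> pd.DataFrame:
    """(FPR, TPR, threshold) at every distinct score threshold, for plotting."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    order = np.argsort(-scores, kind="mergesort")
    s, y = scores[order], (labels[order] == 1).astype(int)
    distinct = np.r_[np.flatnonzero(np.diff(s)), len(s) - 1]
    tps = np.cumsum(y)[distinct]
    fps = distinct + 1 - tps
    n_pos, n_neg = y.sum(), len(y) - y.sum()
    return pd.DataFrame(
        {
            "threshold": np.r_[np.inf, s[distinct]],
            "fpr": np.r_[0.0, fps / max(n_neg, 1)],
            "tpr": np.r_[0.0, tps / max(n_pos, 1)],
        }
    )


def aggregate_folds(fold_aucs) -> tuple[float, float]:
    """Mean over folds and standard error (sample sd / sqrt(k))."""
    vals = np.asarray(list(fold_aucs), dtype=float)
    if vals.size < 2:
        raise ValueError("need at least 2 folds to aggregate")
    return float(vals.mean()), float(vals.std(ddof=1) / np.sqrt(vals.size))


def format_auc(mean: float, se: float) -> str:
    """Presentation format, e.g. ``0.899 (±0.008)``."""
    return f"{mean:.3f} (±{se:.3f})"


@dataclass
class EvalReport:
    """One evaluation scope for one task: per-fold and aggregated AUC."""

    task: str
    scope: str  # "all", "HEvents", "MREvents", "bin_i/n"
    cls: str  # target class ("positive" for binary tasks)
    fold_aucs: dict[int, float]
    mean: float | None
    se: float | None
    n: int
    computable: bool = True

    def formatted(self) -> str:
        if not self.computable or self.mean is None:
            return "NA"
        return format_auc(self.mean, self.se if self.se is not None else 0.0)


def _per_fold_auc(df: pd.DataFrame, score_col: str, label_col: str = "_y") -> dict[int, float]:
    out: dict[int, float] = {}
    for fold, grp in df.groupby("fold"):
        y = grp[label_col].to_numpy()
        if y.min() == y.max():
            continue  # single-class fold in this scope
        out[int(fold)] = roc_auc(grp[score_col].to_numpy(), y)
    return out


def _make_report(task: str, scope: str, cls: str, df: pd.DataFrame, score_col: str) -> EvalReport:
    n = int((df["_y"] == 1).sum())
    fold_aucs = _per_fold_auc(df, score_col)
    if len(fold_aucs) == 0:
        return EvalReport(task, scope, cls, {}, None, None, n, computable=False)
    if len(fold_aucs) == 1:
        (only,) = fold_aucs.values()
        return EvalReport(task, scope, cls, fold_aucs, only, None, n)
    mean, se = aggregate_folds(fold_aucs.values())
    return EvalReport(task, scope, cls, fold_aucs, mean, se, n)


def stratified_report(predictions: pd.DataFrame, task: str) -> list[EvalReport]:
    """AUC reports for the scopes all / MREvents / HEvents.

    *predictions* is the long-format output of the cross-validation
    campaign.  For binary tasks, a stratum keeps every constitutive
    negative and restricts the positives to that stratum.  For DSC each of
    the four classes gets a one-vs-rest AUC on its softmax probability,
    plus their unweighted average as class ``macro``.
    """
    reports: list[EvalReport] = []
    for scope in ("all", "MREvents", "HEvents"):
        if scope == "all":
            df = predictions
        else:
            df = predictions[(predictions["stratum"] == scope) | (predictions["true_label"] == "CON")]
        if task == "DSC":
            per_class: list[EvalReport] = []
            for cls in DSC_CLASSES:
                # one-vs-rest: every row stays, only the target indicator changes
                sub = df.assign(_y=(df["true_label"] == cls).astype(int))
                per_class.append(_make_report(task, scope, cls, sub, f"p_{cls}"))
            reports.extend(per_class)
            computable = [r for r in per_class if r.computable]
            if len(computable) == len(per_class):
                folds = sorted(set.intersection(*(set(r.fold_aucs) for r in per_class)))
                macro_folds = {
                    f: float(np.mean([r.fold_aucs[f] for r in per_class])) for f in folds
                }
                if len(macro_folds) >= 2:
                    mean, se = aggregate_folds(macro_folds.values())
                elif macro_folds:
                    (mean,), se = list(macro_folds.values()), None
                else:
                    mean = se = None
                reports.append(
                    EvalReport(task, scope, "macro", macro_folds, mean, se,
                               int((df["true_label"] != "CON").sum()),
                               computable=mean is not None)
                )
            else:
                reports.append(EvalReport(task, scope, "macro", {}, None, None, 0, computable=False))
        else:
            pos = POSITIVE_CLASS[task]
            sub = df.assign(_y=(df["true_label"] == pos).astype(int))
            reports.append(_make_report(task, scope, pos, sub, "score"))
    return reports


def inclusion_bin_auc(predictions: pd.DataFrame, n_bins: int = 5) -> list[EvalReport]:
    """CON-ES AUC per inclusion-level bin.

    Cassette-exon positives are binned by inclusion level into
    ``[i/n, (i+1)/n)`` intervals (last bin closed at 1); each bin's AUC is
    computed against the full constitutive negative set.
    """
    es = predictions[predictions["true_label"] == "ES"]
    con = predictions[predictions["true_label"] == "CON"]
    reports: list[EvalReport] = []
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    for i in range(n_bins):
        lo, hi = edges[i], edges[i + 1]
        if i == n_bins - 1:
            in_bin = (es["level"] >= lo) & (es["level"] <= hi)
        else:
            in_bin = (es["level"] >= lo) & (es["level"] < hi)
        df = pd.concat([es[in_bin], con], ignore_index=True)
        df = df.assign(_y=(df["true_label"] == "ES").astype(int))
        scope = f"bin_{i + 1}/{n_bins}"
        if in_bin.sum() == 0:
            reports.append(EvalReport("CON-ES", scope, "ES", {}, None, None, 0, computable=False))
        else:
            reports.append(_make_report("CON-ES", scope, "ES", df, "score"))
    return reports


def reports_to_frame(reports: list[EvalReport]) -> pd.DataFrame:
    """Long-format CSV-ready table: one row per (task, scope, class, fold)."""
    rows = []
    for r in reports:
        if not r.fold_aucs:
            rows.append({"task": r.task, "scope": r.scope, "class": r.cls, "fold": None, "auc": None})
        for fold, auc in sorted(r.fold_aucs.items()):
            rows.append({"task": r.task, "scope": r.scope, "class": r.cls, "fold": fold, "auc": auc})
    return pd.DataFrame(rows)
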