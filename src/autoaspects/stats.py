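"""Reader-study evaluation statistics.

Covers the full performance battery used to compare an automated ASPECTS
reader with physicians: confusion-matrix metrics (sensitivity,
specificity, accuracy, precision, F1), Cohen's kappa, the intraclass
correlation coefficient, ROC/AUC, and a paired one-tailed permutation
test of assisted vs. unassisted reader performance.  It also provides
``reconstruct_confusion``, which recovers the integer confusion matrix
behind a published (sensitivity, specificity, accuracy, precision, n)
row by exhaustive search — the bridge that lets printed summary tables
be verified cell by cell.

Printed-value matching uses round-half-away-from-zero at the printed
number of decimals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score, roc_curve

__all__ = ["ConfusionMatrix", "confusion", "basic_metrics", "cohens_kappa",
           "icc_absolute_agreement", "roc_auc", "ReaderStudy",
           "permutation_test_paired", "reconstruct_confusion",
           "ReconstructionResult", "round_half_away", "UndefinedMetricError"]


class UndefinedMetricError(ValueError):
    """A metric's denominator is zero (flagged, never silently NaN)."""


def round_half_away(x: float, decimals: int) -> float:
    """Round half away from zero (the convention of printed clinical tables)."""
    f = 10.0 ** decimals
    return math.copysign(math.floor(abs(x) * f + 0.5), x) / f


@dataclass(frozen=True)
class ConfusionMatrix:
    """TP/FP/FN/TN counts for one binary task."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be nonnegative")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    def __add__(self, other: "ConfusionMatrix") -> "ConfusionMatrix":
        return ConfusionMatrix(self.tp + other.tp, self.fp + other.fp,
                               self.fn + other.fn, self.tn + other.tn)


def confusion(pred, truth) -> ConfusionMatrix:
    """Tally predictions against ground truth (positive = True)."""
    pred = np.asarray(pred, dtype=bool)
    truth = np.asarray(truth, dtype=bool)
    if pred.shape != truth.shape:
        raise ValueError(f"length mismatch: {pred.shape} vs {truth.shape}")
    if pred.size == 0:
        raise ValueError("empty inputs")
    return ConfusionMatrix(tp=int(np.sum(pred & truth)), fp=int(np.sum(pred & ~truth)),
                           fn=int(np.sum(~pred & truth)), tn=int(np.sum(~pred & ~truth)))


def _safe_div(num: float, den: float) -> float | None:
    return num / den if den > 0 else None


def basic_metrics(cm: ConfusionMatrix) -> dict[str, float | None]:
    """Sensitivity, specificity, accuracy, precision and F1.

    A metric whose denominator is zero is returned as ``None`` (undefined)
    rather than NaN.
    """
    if cm.n == 0:
        raise UndefinedMetricError("empty confusion matrix")
    sens = _safe_div(cm.tp, cm.tp + cm.fn)
    spec = _safe_div(cm.tn, cm.tn + cm.fp)
    prec = _safe_div(cm.tp, cm.tp + cm.fp)
    acc = (cm.tp + cm.tn) / cm.n
    if prec is None or sens is None or prec + sens == 0:
        f1 = None if (prec is None or sens is None) else 0.0
    else:
        f1 = 2.0 * prec * sens / (prec + sens)
    return {"sensitivity": sens, "specificity": spec, "accuracy": acc,
            "precision": prec, "f1": f1}


def cohens_kappa(cm: ConfusionMatrix) -> float:
    """Chance-corrected agreement for a 2x2 table.

    ``kappa = (po - pe) / (1 - pe)`` with observed agreement
    ``po = (tp+tn)/n`` and chance agreement from the marginals.  Perfect
    agreement with degenerate marginals (pe = 1, po = 1) returns 1.0;
    pe = 1 with po < 1 is undefined and raises.
    """
    n = cm.n
    if n == 0:
        raise UndefinedMetricError("empty confusion matrix")
    po = (cm.tp + cm.tn) / n
    pe = ((cm.tp + cm.fp) * (cm.tp + cm.fn) + (cm.fn + cm.tn) * (cm.fp + cm.tn)) / n ** 2
    if pe >= 1.0 - 1e-15:
        if po >= 1.0 - 1e-15:
            return 1.0
        raise UndefinedMetricError("kappa undefined: chance agreement is 1 with po < 1")
    return (po - pe) / (1.0 - pe)


def icc_absolute_agreement(ratings, form: str = "ICC2") -> float:
    """Single-measure intraclass correlation from a cases x raters matrix.

    ``form='ICC2'`` (default): two-way random effects, absolute agreement,
    single rater — ICC(2,1).  ``form='ICC3'``: two-way mixed, consistency,
    ICC(3,1).  Computed from the standard ANOVA mean squares.
    """
    x = np.asarray(ratings, dtype=np.float64)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise ValueError("ratings must be a cases x raters matrix with >= 2 of each")
    if np.isnan(x).any():
        raise ValueError("missing cells are not supported")
    n, k = x.shape
    grand = x.mean()
    row_m = x.mean(axis=1)
    col_m = x.mean(axis=0)
    ss_rows = k * np.sum((row_m - grand) ** 2)
    ss_cols = n * np.sum((col_m - grand) ** 2)
    ss_tot = np.sum((x - grand) ** 2)
    ss_err = ss_tot - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    if ss_tot <= 1e-30:
        raise UndefinedMetricError("ICC undefined: zero total variance")
    if form == "ICC2":
        denom = msr + (k - 1) * mse + k * (msc - mse) / n
    elif form == "ICC3":
        denom = msr + (k - 1) * mse
    else:
        raise ValueError(f"unknown ICC form {form!r}; use 'ICC2' or 'ICC3'")
    if denom <= 0:
        raise UndefinedMetricError("ICC undefined: nonpositive denominator")
    return float((msr - mse) / denom)


def roc_auc(scores, labels) -> dict:
    """ROC staircase and AUC (equal to the Mann-Whitney statistic with ties
    counted one half)."""
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels, dtype=bool)
    if labels.all() or not labels.any():
        raise ValueError("ROC requires both classes present")
    fpr, tpr, thr = roc_curve(labels.astype(int), scores)
    return {"fpr": fpr, "tpr": tpr, "thresholds": thr,
            "auc": float(roc_auc_score(labels.astype(int), scores))}


# -- paired permutation test ----------------------------------------------

@dataclass
class ReaderStudy:
    """Per-case decisions of each reader under two conditions.

    ``data`` is a long-format table with columns
    ``case, reader, condition, decision, truth`` where condition is
    ``"alone"`` or ``"with_dlad"``.  Extra columns (e.g. region) may be
    present; cases are whatever unit the paired test should resample.
    """

    data: pd.DataFrame
    CONDITIONS = ("alone", "with_dlad")

    def __post_init__(self):
        required = {"case", "reader", "condition", "decision", "truth"}
        missing = required - set(self.data.columns)
        if missing:
            raise ValueError(f"reader study table missing columns {sorted(missing)}")

    def paired_arrays(self, reader) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(alone, with_dlad, truth) decision arrays aligned by case."""
        sub = self.data[self.data["reader"] == reader]
        if sub.empty:
            raise ValueError(f"unknown reader {reader!r}")
        piv = sub.pivot_table(index="case", columns="condition",
                              values=["decision", "truth"], aggfunc="first")
        for cond in self.CONDITIONS:
            if ("decision", cond) not in piv.columns or piv[("decision", cond)].isna().any():
                raise ValueError(f"reader {reader!r} lacks condition {cond!r} for some cases")
        alone = piv[("decision", "alone")].to_numpy(dtype=bool)
        assisted = piv[("decision", "with_dlad")].to_numpy(dtype=bool)
        truth = piv[("truth", "alone")].to_numpy(dtype=bool)
        return alone, assisted, truth


def permutation_test_paired(metric, study: ReaderStudy, reader, n_perm: int = 10_000,
                            seed: int | np.random.Generator = 0) -> dict:
    """One-tailed paired permutation test of assisted minus unassisted
    performance.

    The observed statistic is ``metric(with_dlad, truth) -
    metric(alone, truth)``.  The null swaps the two condition labels
    independently within each case with probability 1/2.  The p-value uses
    add-one smoothing: ``(1 + #{perm >= observed}) / (1 + n_perm)``.
    Permutations on which the metric is undefined are redrawn and counted
    in the returned ``n_resampled``.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    alone, assisted, truth = study.paired_arrays(reader)
    observed = metric(assisted, truth) - metric(alone, truth)
    count = 0
    n_resampled = 0
    done = 0
    while done < n_perm:
        swap = rng.random(alone.size) < 0.5
        a = np.where(swap, assisted, alone)
        b = np.where(swap, alone, assisted)
        try:
            stat = metric(b, truth) - metric(a, truth)
        except (UndefinedMetricError, ZeroDivisionError):
            n_resampled += 1
            continue
        if stat >= observed - 1e-12:
            count += 1
        done += 1
    return {"observed": float(observed), "p_value": (1 + count) / (1 + n_perm),
            "n_perm": n_perm, "n_resampled": n_resampled}


def sensitivity_metric(decisions, truth) -> float:
    """Sensitivity as a bare function, suitable for the permutation test."""
    truth = np.asarray(truth, dtype=bool)
    if not truth.any():
        raise UndefinedMetricError("no positive cases")
    return float(np.mean(np.asarray(decisions, dtype=bool)[truth]))


def accuracy_metric(decisions, truth) -> float:
    return float(np.mean(np.asarray(decisions, dtype=bool) == np.asarray(truth, dtype=bool)))


# -- confusion-matrix reconstruction from printed metrics ------------------

@dataclass
class ReconstructionResult:
    matrices: list[ConfusionMatrix]
    closest: ConfusionMatrix | None = None

    @property
    def unique(self) -> bool:
        return len(self.matrices) == 1

    @property
    def matrix(self) -> ConfusionMatrix:
        if not self.matrices:
            raise ValueError("no consistent confusion matrix found; "
                             f"closest candidate: {self.closest}")
        if not self.unique:
            raise ValueError(f"{len(self.matrices)} consistent matrices; ambiguous")
        return self.matrices[0]


def reconstruct_confusion(sens: float, spec: float, acc: float, prec: float,
                          n: int, decimals: int = 3) -> ReconstructionResult:
    """Recover integer (tp, fp, fn, tn) from metrics printed to ``decimals``
    decimal places (as fractions; 40.9% -> 0.409 with decimals=3).

    Exhaustively enumerates every split of ``n`` and keeps the matrices
    whose recomputed metrics round (half away from zero) to the reported
    values.  When nothing matches, the closest candidate by summed metric
    error is returned for diagnosis.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    for name, v in (("sens", sens), ("spec", spec), ("acc", acc), ("prec", prec)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} must be in [0, 1], got {v}")
    matches: list[ConfusionMatrix] = []
    best = None
    best_err = np.inf
    for pos in range(n + 1):
        neg = n - pos
        tp = np.arange(pos + 1)[:, None]
        fp = np.arange(neg + 1)[None, :]
        fn = pos - tp
        tn = neg - fp
        with np.errstate(divide="ignore", invalid="ignore"):
            m_sens = np.where(pos > 0, tp / max(pos, 1), np.nan) * np.ones_like(fp, dtype=float)
            m_spec = np.ones_like(tp, dtype=float) * np.where(neg > 0, tn / max(neg, 1), np.nan)
            m_acc = (tp + tn) / n
            denom = tp + fp
            m_prec = np.where(denom > 0, tp / np.maximum(denom, 1), np.nan)
        f = 10.0 ** decimals

        def rounds_to(vals, target):
            return np.floor(np.abs(vals) * f + 0.5) / f == round_half_away(target, decimals)

        ok = (rounds_to(m_sens, sens) & rounds_to(m_spec, spec)
              & rounds_to(m_acc, acc) & rounds_to(m_prec, prec))
        ok &= ~np.isnan(m_sens) & ~np.isnan(m_spec) & ~np.isnan(m_prec)
        for i, j in zip(*np.nonzero(ok)):
            matches.append(ConfusionMatrix(tp=int(tp[i, 0]), fp=int(fp[0, j]),
                                           fn=int(fn[i, 0]), tn=int(tn[0, j])))
        err = (np.abs(np.nan_to_num(m_sens, nan=2.0) - sens)
               + np.abs(np.nan_to_num(m_spec, nan=2.0) - spec)
               + np.abs(m_acc - acc)
               + np.abs(np.nan_to_num(m_prec, nan=2.0) - prec))
        k = int(np.argmin(err))
        i, j = np.unravel_index(k, err.shape)
        if err[i, j] < best_err:
            best_err = err[i, j]
            best = ConfusionMatrix(tp=int(tp[i, 0]), fp=int(fp[0, j]),
                                   fn=int(fn[i, 0]), tn=int(tn[0, j]))
    return ReconstructionResult(matrices=matches, closest=best)
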