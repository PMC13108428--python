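"""Metric families for the pain cascade.

Classification metrics (pain = positive class throughout), ROC/PR AUC with
stratified-bootstrap percentile confidence intervals, regression metrics
with CoVAS tolerance bands, per-pain-stratum performance (mild 1-30,
moderate 31-70, severe 71-100, plus specificity on the no-pain stratum),
and Bland-Altman agreement (bias +/- 1.96 x sample SD of differences).
Undefined ratios (zero denominators) are reported as NaN, never as 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sp_stats
from sklearn.metrics import average_precision_score, roc_auc_score

from ._rng import rng_for
from .errors import ValidationError

__all__ = [
    "ClassificationReport",
    "RegressionReport",
    "BlandAltmanResult",
    "classification_metrics",
    "auc_with_ci",
    "regression_metrics",
    "stratified_metrics",
    "bland_altman",
    "DEFAULT_STRATA",
]

#: (low, high, name) CoVAS strata; membership is low <= covas <= high.
DEFAULT_STRATA: tuple[tuple[float, float, str], ...] = (
    (0.0, 0.0, "no_pain"),
    (1.0, 30.0, "mild"),
    (31.0, 70.0, "moderate"),
    (71.0, 100.0, "severe"),
)


@dataclass
class ClassificationReport:
    accuracy: float
    precision: float
    recall: float
    specificity: float
    f1: float
    mcc: float
    cohen_kappa: float
    confusion: np.ndarray  # [[TN, FP], [FN, TP]]
    auc_roc: tuple[float, float, float] | None = None  # (value, lo, hi)
    auc_pr: tuple[float, float, float] | None = None

    def as_dict(self) -> dict:
        out = {
            "accuracy": self.accuracy,
            "precision": self.precision,
            "recall": self.recall,
            "specificity": self.specificity,
            "f1": self.f1,
            "mcc": self.mcc,
            "cohen_kappa": self.cohen_kappa,
            "confusion": self.confusion.tolist(),
        }
        if self.auc_roc is not None:
            out["auc_roc"] = list(self.auc_roc)
        if self.auc_pr is not None:
            out["auc_pr"] = list(self.auc_pr)
        return out


@dataclass
class RegressionReport:
    mae: float
    rmse: float
    mape_pct: float
    r2: float
    mean_bias: float
    resid_sd: float
    pct_within_5: float
    pct_within_10: float
    pct_within_15: float

    def as_dict(self) -> dict:
        return dict(self.__dict__)


@dataclass
class BlandAltmanResult:
    bias: float
    loa_low: float
    loa_high: float
    pct_within_loa: float
    proportional_bias_r: float
    diffs: np.ndarray = field(repr=False, default=None)
    means: np.ndarray = field(repr=False, default=None)

    def as_dict(self) -> dict:
        return {
            "bias": self.bias,
            "loa_low": self.loa_low,
            "loa_high": self.loa_high,
            "pct_within_loa": self.pct_within_loa,
            "proportional_bias_r": self.proportional_bias_r,
        }


def _safe_div(num: float, den: float) -> float:
    return num / den if den > 0 else float("nan")


def classification_metrics(true_labels, pred_labels) -> ClassificationReport:
    """Standard binary metrics from the 2x2 table, pain (1) as the positive class."""
    y = np.asarray(true_labels).astype(int)
    p = np.asarray(pred_labels).astype(int)
    if y.size == 0:
        raise ValidationError("empty inputs")
    if y.shape != p.shape:
        raise ValidationError("label vectors must have the same length")
    tp = int(np.sum((y == 1) & (p == 1)))
    tn = int(np.sum((y == 0) & (p == 0)))
    fp = int(np.sum((y == 0) & (p == 1)))
    fn = int(np.sum((y == 1) & (p == 0)))
    n = tp + tn + fp + fn
    precision = _safe_div(tp, tp + fp)
    recall = _safe_div(tp, tp + fn)
    specificity = _safe_div(tn, tn + fp)
    f1 = (
        _safe_div(2 * precision * recall, precision + recall)
        if not (math.isnan(precision) or math.isnan(recall))
        else float("nan")
    )
    mcc_den = math.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    mcc = (tp * tn - fp * fn) / mcc_den if mcc_den > 0 else float("nan")
    po = (tp + tn) / n
    pe = ((tp + fp) * (tp + fn) + (tn + fn) * (tn + fp)) / (n * n)
    kappa = (po - pe) / (1 - pe) if pe < 1 else float("nan")
    return ClassificationReport(
        accuracy=po,
        precision=precision,
        recall=recall,
        specificity=specificity,
        f1=f1,
        mcc=mcc,
        cohen_kappa=kappa,
        confusion=np.array([[tn, fp], [fn, tp]]),
    )


def auc_with_ci(
    true_labels,
    scores,
    curve: str = "roc",
    n_boot: int = 2000,
    seed: int = 0,
    ci: float = 0.95,
) -> tuple[float, float, float]:
    """AUC with a stratified-bootstrap percentile confidence interval.

    ROC AUC is the rank statistic (ties get half credit); PR AUC is average
    precision. Bootstrap resamples each class separately so every replicate
    keeps both classes.
    """
    y = np.asarray(true_labels).astype(int)
    s = np.asarray(scores, dtype=float)
    if len(np.unique(y)) < 2:
        raise ValidationError("both classes must be present for AUC")
    if curve == "roc":
        stat = roc_auc_score
    elif curve == "pr":
        stat = average_precision_score
    else:
        raise ValidationError("curve must be 'roc' or 'pr'")
    value = float(stat(y, s))
    pos = np.flatnonzero(y == 1)
    neg = np.flatnonzero(y == 0)
    rng = rng_for(seed, f"auc-{curve}")
    boots = np.empty(n_boot)
    for b in range(n_boot):
        idx = np.concatenate(
            [rng.choice(pos, size=len(pos)), rng.choice(neg, size=len(neg))]
        )
        boots[b] = stat(y[idx], s[idx])
    alpha = (1 - ci) / 2
    lo, hi = np.percentile(boots, [100 * alpha, 100 * (1 - alpha)])
    return value, float(lo), float(hi)


def regression_metrics(actual, predicted) -> RegressionReport:
    """MAE, RMSE, MAPE, R^2, bias, residual SD and CoVAS tolerance bands.

    MAPE is NaN-flagged when any actual value is 0 (the cascade regressor
    only ever sees CoVAS > 0 rows, so that flags misuse rather than data).
    Tolerance bands use |error| <= threshold.
    """
    a = np.asarray(actual, dtype=float)
    p = np.asarray(predicted, dtype=float)
    if a.size == 0 or a.shape != p.shape:
        raise ValidationError("actual and predicted must be equal-length and non-empty")
    err = p - a
    mae = float(np.mean(np.abs(err)))
    rmse = float(np.sqrt(np.mean(err**2)))
    mape = float(100.0 * np.mean(np.abs(err) / a)) if np.all(a > 0) else float("nan")
    ss_res = float(np.sum(err**2))
    ss_tot = float(np.sum((a - a.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")
    within = lambda tol: float(100.0 * np.mean(np.abs(err) <= tol))
    return RegressionReport(
        mae=mae,
        rmse=rmse,
        mape_pct=mape,
        r2=r2,
        mean_bias=float(err.mean()),
        resid_sd=float(err.std(ddof=1)) if err.size > 1 else 0.0,
        pct_within_5=within(5.0),
        pct_within_10=within(10.0),
        pct_within_15=within(15.0),
    )


def _stratum_of(covas: np.ndarray, strata) -> np.ndarray:
    """Assign each CoVAS value to a stratum.

    Bounds are integer-labeled (mild 1-30, moderate 31-70 ...) but CoVAS is
    continuous, so membership runs on upper edges: the first stratum covers
    its closed interval and each later stratum covers (previous hi, hi].
    """
    ordered = sorted(strata, key=lambda s: s[0])
    names = np.empty(covas.shape, dtype=object)
    lo0, hi0, name0 = ordered[0]
    names[(covas >= lo0) & (covas <= hi0)] = name0
    prev_hi = hi0
    for lo, hi, name in ordered[1:]:
        names[(covas > prev_hi) & (covas <= hi)] = name
        prev_hi = hi
    return names


def stratified_metrics(
    actual_covas,
    pred_pain_label,
    pred_intensity=None,
    strata=DEFAULT_STRATA,
) -> pd.DataFrame:
    """Per-pain-stratum precision/recall; specificity for the no-pain stratum.

    Rows are assigned to strata by *actual* CoVAS. Pain strata are scored as
    one-vs-rest membership of the stratum the predicted intensity falls in;
    the no-pain row reports the binary label's specificity. Empty strata get
    NaN-flagged rows.
    """
    a = np.asarray(actual_covas, dtype=float)
    label = np.asarray(pred_pain_label).astype(int)
    intensity = np.asarray(pred_intensity, dtype=float) if pred_intensity is not None else None
    for i, (lo1, hi1, n1) in enumerate(strata):
        for lo2, hi2, n2 in strata[i + 1 :]:
            if max(lo1, lo2) <= min(hi1, hi2):
                raise ValidationError(f"strata {n1!r} and {n2!r} overlap")
    ordered = sorted(strata, key=lambda s: s[0])
    if ordered[0][0] > 0 or ordered[-1][1] < 100:
        raise ValidationError("strata must cover the 0-100 CoVAS range")

    actual_stratum = _stratum_of(a, strata)
    pred_stratum = None
    if intensity is not None:
        pred_covas = np.where(label == 1, intensity, 0.0)
        pred_stratum = _stratum_of(pred_covas, strata)

    rows = []
    for lo, hi, name in strata:
        members = actual_stratum == name
        n = int(members.sum())
        row: dict = {"stratum": name, "covas_low": lo, "covas_high": hi, "n": n}
        if n == 0:
            row.update(precision=np.nan, recall=np.nan, specificity=np.nan)
        elif name == "no_pain":
            row.update(
                precision=np.nan,
                recall=np.nan,
                specificity=float(np.mean(label[members] == 0)),
            )
        elif pred_stratum is not None:
            tp = int(np.sum(members & (pred_stratum == name)))
            pp = int(np.sum(pred_stratum == name))
            row.update(
                precision=_safe_div(tp, pp),
                recall=tp / n,
                specificity=np.nan,
            )
        else:  # detection-only view: recall = pain detection rate in the stratum
            row.update(
                precision=np.nan,
                recall=float(np.mean(label[members] == 1)),
                specificity=np.nan,
            )
        rows.append(row)
    return pd.DataFrame(rows)


def bland_altman(actual, predicted) -> BlandAltmanResult:
    """Agreement between predicted and actual intensity: bias +/- 1.96 SD of differences.

    diff = predicted - actual; limits of agreement use the sample (n-1) SD.
    ``pct_within_loa`` counts points inside or on the limits;
    ``proportional_bias_r`` is the Pearson correlation between pair means
    and differences (NaN when either is constant).
    """
    a = np.asarray(actual, dtype=float)
    p = np.asarray(predicted, dtype=float)
    if a.size < 3:
        raise ValidationError("Bland-Altman needs at least 3 pairs")
    diff = p - a
    mean = (p + a) / 2.0
    bias = float(diff.mean())
    sd = float(diff.std(ddof=1))
    loa_low, loa_high = bias - 1.96 * sd, bias + 1.96 * sd
    within = float(100.0 * np.mean((diff >= loa_low) & (diff <= loa_high)))
    if np.ptp(diff) == 0 or np.ptp(mean) == 0:
        r = float("nan")
    else:
        r = float(sp_stats.pearsonr(mean, diff)[0])
    return BlandAltmanResult(
        bias=bias,
        loa_low=loa_low,
        loa_high=loa_high,
        pct_within_loa=within,
        proportional_bias_r=r,
        diffs=diff,
        means=mean,
    )
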