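"""Logistic-regression classification and evaluation of feature tables.

Binary segment labels are predicted from the spectral feature vectors
with unpenalised logistic regression on z-scored features, so fitted
coefficients translate directly into odds ratios.  Evaluation follows the
standard battery: accuracy and F-measure at the 0.5 probability
threshold, ROC-AUC and precision-recall curves over all thresholds, and a
5-fold repeated-test-set protocol (stratified disjoint folds from one
seeded shuffle) summarised as mean +/- sd per metric.  Per-feature odds
ratios with Wald 95% confidence intervals and p-values come from a
statsmodels logit fit on the standardised design.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Tuple

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import auc as sk_auc
from sklearn.metrics import precision_recall_curve, roc_curve
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler

from .errors import ValidationError

LABEL_COLUMN = "label"


def split_xy(table: pd.DataFrame) -> Tuple[pd.DataFrame, np.ndarray]:
    """Feature matrix and 0/1 label vector from a feature table."""
    if LABEL_COLUMN not in table.columns:
        raise ValidationError(f"feature table lacks a {LABEL_COLUMN!r} column")
    X = table.drop(columns=[LABEL_COLUMN])
    if X.isna().any().any():
        raise ValidationError("feature table contains missing values")
    y = table[LABEL_COLUMN].to_numpy()
    classes = np.unique(y)
    if classes.size != 2:
        raise ValidationError(f"need exactly two classes, got {classes}")
    return X, (y == classes.max()).astype(int)


@dataclass(frozen=True)
class EvalReport:
    """Threshold-0.5 and curve metrics on one test set."""

    accuracy: float
    auc: float
    f_measure: float
    precision: float
    recall: float
    confusion: Tuple[int, int, int, int]  # tn, fp, fn, tp
    roc: pd.DataFrame = field(repr=False)  # columns fpr, tpr
    pr: pd.DataFrame = field(repr=False)  # columns recall, precision

    def to_dict(self) -> dict:
        tn, fp, fn, tp = self.confusion
        return {
            "accuracy": self.accuracy,
            "auc": self.auc,
            "f_measure": self.f_measure,
            "precision": self.precision,
            "recall": self.recall,
            "confusion": {"tn": tn, "fp": fp, "fn": fn, "tp": tp},
        }


def fit_logistic(features: pd.DataFrame, C: float = 1e8, max_iter: int = 5000) -> Pipeline:
    """Fit z-scored, effectively-unpenalised logistic regression.

    A tiny ridge (``1/C``) keeps the solver stable on separable data
    without materially shrinking coefficients.
    """
    X, y = split_xy(features)
    if min(np.bincount(y)) < 2:
        raise ValidationError("need at least 2 samples per class to fit")
    model = Pipeline(
        [
            ("scale", StandardScaler()),
            (
                "logit",
                LogisticRegression(C=C, solver="lbfgs", max_iter=max_iter, tol=1e-10),
            ),
        ]
    )
    model.fit(X.to_numpy(), y)
    return model


def f_measure(precision: float, recall: float) -> float:
    """Harmonic mean ``2PR / (P + R)``; zero when both rates are zero."""
    if precision + recall == 0.0:
        return 0.0
    return 2.0 * precision * recall / (precision + recall)


def evaluate(model: Pipeline, test_features: pd.DataFrame) -> EvalReport:
    """Score a fitted model on a held-out feature table."""
    X, y = split_xy(test_features)
    if len(np.unique(y)) < 2:
        raise ValidationError("AUC undefined on a single-class test set")
    scores = model.predict_proba(X.to_numpy())[:, 1]
    pred = (scores >= 0.5).astype(int)

    tp = int(np.sum((pred == 1) & (y == 1)))
    fp = int(np.sum((pred == 1) & (y == 0)))
    fn = int(np.sum((pred == 0) & (y == 1)))
    tn = int(np.sum((pred == 0) & (y == 0)))
    accuracy = (tp + tn) / y.size
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0

    fpr, tpr, _ = roc_curve(y, scores)
    rec, prec, _ = precision_recall_curve(y, scores)
    return EvalReport(
        accuracy=float(accuracy),
        auc=float(sk_auc(fpr, tpr)),
        f_measure=f_measure(precision, recall),
        precision=float(precision),
        recall=float(recall),
        confusion=(tn, fp, fn, tp),
        roc=pd.DataFrame({"fpr": fpr, "tpr": tpr}),
        pr=pd.DataFrame({"recall": rec, "precision": prec}),
    )


def repeated_splits(
    features: pd.DataFrame, n_repeats: int = 5, seed: int = 0
) -> Tuple[List[EvalReport], pd.DataFrame]:
    """Repeated held-out testing over disjoint stratified folds.

    One seeded shuffle defines ``n_repeats`` disjoint stratified test
    folds; each repeat trains on the complement and tests on one fold.
    Returns the per-fold reports and a mean +/- sd summary frame.
    """
    X, y = split_xy(features)
    if min(np.bincount(y)) < n_repeats:
        raise ValidationError(
            f"each class needs at least {n_repeats} samples for {n_repeats} stratified folds"
        )
    skf = StratifiedKFold(n_splits=n_repeats, shuffle=True, random_state=seed)
    reports = []
    for train_idx, test_idx in skf.split(X, y):
        model = fit_logistic(features.iloc[train_idx])
        reports.append(evaluate(model, features.iloc[test_idx]))
    rows = pd.DataFrame(
        [
            {"accuracy": r.accuracy, "auc": r.auc, "f_measure": r.f_measure}
            for r in reports
        ]
    )
    summary = pd.DataFrame({"mean": rows.mean(), "sd": rows.std(ddof=1)})
    return reports, summary


def odds_ratios(
    features: pd.DataFrame, mode: str = "multivariate"
) -> pd.DataFrame:
    """Per-feature odds ratios with Wald 95% CIs from a standardised logit fit.

    ``mode='multivariate'`` fits all features jointly; ``'univariate'``
    fits one logit per feature.  Features involved in exact collinearity
    or non-convergence are flagged in the ``flag`` column instead of
    aborting the whole analysis.
    """
    if mode not in ("multivariate", "univariate"):
        raise ValidationError(f"unknown odds-ratio mode {mode!r}")
    X, y = split_xy(features)
    Z = (X - X.mean()) / X.std(ddof=0).replace(0.0, 1.0)

    flags = {name: "" for name in X.columns}
    # exact duplicates / constant columns make Wald inference meaningless
    arr = Z.to_numpy()
    for i, a in enumerate(X.columns):
        if X[a].std(ddof=0) == 0.0:
            flags[a] = "constant"
            continue
        for b in X.columns[i + 1 :]:
            if np.allclose(arr[:, i], Z[b].to_numpy()):
                flags[a] = flags[b] = "collinear"

    def _fit(design: pd.DataFrame):
        exog = sm.add_constant(design, has_constant="add")
        try:
            with np.errstate(all="ignore"):
                res = sm.Logit(y, exog).fit(disp=0, maxiter=200)
            if not res.mle_retvals.get("converged", False):
                return None
            return res
        except Exception:
            return None

    records = []
    if mode == "multivariate":
        fit = _fit(Z)
        for name in X.columns:
            rec = {"feature": name, "flag": flags[name]}
            if fit is not None and name in fit.params.index:
                coef = fit.params[name]
                se = fit.bse[name]
                rec.update(
                    coefficient=coef,
                    odds_ratio=float(np.exp(coef)),
                    ci_low=float(np.exp(coef - 1.959963984540054 * se)),
                    ci_high=float(np.exp(coef + 1.959963984540054 * se)),
                    p=float(fit.pvalues[name]),
                )
            else:
                rec["flag"] = (rec["flag"] + ";nonconverged").strip(";")
                rec.update(coefficient=np.nan, odds_ratio=np.nan,
                           ci_low=np.nan, ci_high=np.nan, p=np.nan)
            records.append(rec)
    else:
        for name in X.columns:
            fit = _fit(Z[[name]])
            rec = {"feature": name, "flag": flags[name]}
            if fit is not None:
                coef = fit.params[name]
                se = fit.bse[name]
                rec.update(
                    coefficient=coef,
                    odds_ratio=float(np.exp(coef)),
                    ci_low=float(np.exp(coef - 1.959963984540054 * se)),
                    ci_high=float(np.exp(coef + 1.959963984540054 * se)),
                    p=float(fit.pvalues[name]),
                )
            else:
                rec["flag"] = (rec["flag"] + ";nonconverged").strip(";")
                rec.update(coefficient=np.nan, odds_ratio=np.nan,
                           ci_low=np.nan, ci_high=np.nan, p=np.nan)
            records.append(rec)
    return pd.DataFrame.from_records(records).set_index("feature")


def compare_method_metrics(metric_table: pd.DataFrame, reference: str) -> pd.DataFrame:
    """Thin helper: nonparametric comparison of per-fold metric columns.

    Runs Levene's test across methods, a Kruskal-Wallis omnibus test and
    Wilcoxon rank-sum tests of ``reference`` against every other column
    with a x(k-1) Bonferroni factor, reporting the rank-biserial effect
    size r.  This is standard significance testing over metric tables, not
    part of the decomposition method.
    """
    others = [c for c in metric_table.columns if c != reference]
    if not others:
        raise ValidationError("need at least two method columns to compare")
    groups = [metric_table[c].to_numpy() for c in metric_table.columns]
    levene_p = stats.levene(*groups).pvalue
    kruskal_p = stats.kruskal(*groups).pvalue
    rows = []
    ref = metric_table[reference].to_numpy()
    for c in others:
        other = metric_table[c].to_numpy()
        res = stats.mannwhitneyu(ref, other, alternative="two-sided")
        n1, n2 = ref.size, other.size
        z = stats.norm.isf(res.pvalue / 2.0) * np.sign(res.statistic - n1 * n2 / 2.0)
        rows.append(
            {
                "method": c,
                "levene_p": levene_p,
                "kruskal_p": kruskal_p,
                "p_bonferroni": min(1.0, res.pvalue * len(others)),
                "effect_size_r": float(z / np.sqrt(n1 + n2)),
            }
        )
    return pd.DataFrame(rows).set_index("method")
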