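"""Probability-level model fusion and the discrimination/calibration battery.

The two branch classifiers (CT and PET) each emit per-subject positive-class
probabilities; a multivariable logistic regression on those two probability
streams gives the fused score.  Evaluation covers AUC with a DeLong 95% CI,
threshold metrics from the 2x2 table, the paired DeLong test for correlated
AUCs, the integrated discrimination improvement (IDI) and the
Hosmer-Lemeshow calibration test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "mann_whitney_auc", "roc_auc_ci", "threshold_metrics", "youden_threshold",
    "delong_test", "idi", "hosmer_lemeshow", "ProbabilityFusion",
    "FusionResults", "fit_fusion", "EvalReport", "evaluate",
]


def _check_binary(labels: np.ndarray) -> np.ndarray:
    y = np.asarray(labels, dtype=int)
    if set(np.unique(y)) - {0, 1}:
        raise ValueError("labels must be 0/1")
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    return y


def mann_whitney_auc(scores, labels) -> float:
    """AUC as the probability a positive outranks a negative (ties count 1/2)."""
    y = _check_binary(labels)
    s = np.asarray(scores, dtype=float)
    pos = s[y == 1][:, None]
    neg = s[y == 0][None, :]
    return float((pos > neg).mean() + 0.5 * (pos == neg).mean())


def _delong_components(scores: np.ndarray, y: np.ndarray):
    """Placement values V10 (per positive) and V01 (per negative)."""
    pos = scores[y == 1]
    neg = scores[y == 0]
    v10 = np.array([((p > neg).sum() + 0.5 * (p == neg).sum()) / len(neg) for p in pos])
    v01 = np.array([((pos > n).sum() + 0.5 * (pos == n).sum()) / len(pos) for n in neg])
    return v10, v01


def roc_auc_ci(scores, labels, level: float = 0.95):
    """AUC with its DeLong confidence interval, clipped to [0, 1]."""
    y = _check_binary(labels)
    s = np.asarray(scores, dtype=float)
    v10, v01 = _delong_components(s, y)
    auc = float(v10.mean())
    var = (np.var(v10, ddof=1) / len(v10) if len(v10) > 1 else 0.0) + \
          (np.var(v01, ddof=1) / len(v01) if len(v01) > 1 else 0.0)
    z = stats.norm.ppf(0.5 + level / 2)
    half = z * np.sqrt(var)
    return auc, float(max(auc - half, 0.0)), float(min(auc + half, 1.0))


def threshold_metrics(scores, labels, threshold: float) -> dict:
    """Accuracy, sensitivity, specificity, PPV and NPV from the 2x2 table.

    Predictions are positive when ``score >= threshold``.  Undefined rates
    (0/0) are reported as 0 by convention.
    """
    y = np.asarray(labels, dtype=int)
    s = np.asarray(scores, dtype=float)
    pred = (s >= threshold).astype(int)
    tp = int(((pred == 1) & (y == 1)).sum())
    fp = int(((pred == 1) & (y == 0)).sum())
    fn = int(((pred == 0) & (y == 1)).sum())
    tn = int(((pred == 0) & (y == 0)).sum())

    def _rate(num, den):
        return num / den if den > 0 else 0.0

    return {
        "tp": tp, "fp": fp, "fn": fn, "tn": tn,
        "accuracy": _rate(tp + tn, tp + fp + fn + tn),
        "sensitivity": _rate(tp, tp + fn),
        "specificity": _rate(tn, tn + fp),
        "ppv": _rate(tp, tp + fp),
        "npv": _rate(tn, tn + fn),
    }


def youden_threshold(scores, labels) -> float:
    """Operating threshold maximizing Youden's J = sens + spec - 1."""
    y = _check_binary(labels)
    s = np.asarray(scores, dtype=float)
    best_t, best_j = 0.5, -np.inf
    for t in np.unique(s):
        m = threshold_metrics(s, y, t)
        j = m["sensitivity"] + m["specificity"] - 1
        if j > best_j:
            best_j, best_t = j, float(t)
    return best_t


def delong_test(scores_a, scores_b, labels):
    """Two-sided paired DeLong comparison of two correlated AUCs.

    Returns ``(z, p)``.  Identical score vectors give z = 0, p = 1.
    """
    y = _check_binary(labels)
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if a.shape != b.shape or len(a) != len(y):
        raise ValueError("paired scores must align with labels")
    va10, va01 = _delong_components(a, y)
    vb10, vb01 = _delong_components(b, y)
    auc_a, auc_b = va10.mean(), vb10.mean()
    m, n = len(va10), len(va01)
    s10 = np.cov(np.stack([va10, vb10]), ddof=1) if m > 1 else np.zeros((2, 2))
    s01 = np.cov(np.stack([va01, vb01]), ddof=1) if n > 1 else np.zeros((2, 2))
    S = s10 / m + s01 / n
    var = S[0, 0] + S[1, 1] - 2 * S[0, 1]
    diff = auc_a - auc_b
    if var <= 0:
        if abs(diff) < 1e-12:
            return 0.0, 1.0
        return float(np.sign(diff) * np.inf), 0.0
    z = diff / np.sqrt(var)
    return float(z), float(2 * stats.norm.sf(abs(z)))


def idi(p_new, p_old, labels):
    """Integrated discrimination improvement with its asymptotic z-test.

    IDI = (discrimination slope of the new model) - (slope of the old one),
    where a slope is mean p among positives minus mean p among negatives.
    """
    y = _check_binary(labels)
    pn = np.asarray(p_new, dtype=float)
    po = np.asarray(p_old, dtype=float)
    if pn.shape != po.shape or len(pn) != len(y):
        raise ValueError("paired probabilities must align with labels")
    d = pn - po
    d_pos, d_neg = d[y == 1], d[y == 0]
    est = float(d_pos.mean() - d_neg.mean())
    se = np.sqrt(
        (np.var(d_pos, ddof=1) / len(d_pos) if len(d_pos) > 1 else 0.0)
        + (np.var(d_neg, ddof=1) / len(d_neg) if len(d_neg) > 1 else 0.0)
    )
    if se == 0:
        return est, (1.0 if est == 0 else 0.0)
    z = est / se
    return est, float(2 * stats.norm.sf(abs(z)))


def hosmer_lemeshow(p, labels, g: int = 10):
    """Hosmer-Lemeshow decile-of-risk calibration test.

    Subjects are split into ``g`` near-equal groups by predicted risk (stable
    sort, so ties keep input order); the chi-square statistic over observed
    vs expected events has g' - 2 degrees of freedom where g' counts
    non-empty groups after collapsing.
    """
    y = np.asarray(labels, dtype=int)
    pr = np.asarray(p, dtype=float)
    if g < 2:
        raise ValueError("need at least two groups")
    if len(pr) < 2 * g:
        raise ValueError("need at least 2 observations per group")
    order = np.argsort(pr, kind="stable")
    groups = np.array_split(order, g)
    groups = [gr for gr in groups if len(gr)]
    if len(groups) < g:
        warnings.warn("empty risk groups collapsed", stacklevel=2)
    stat = 0.0
    used = 0
    for gr in groups:
        e1 = pr[gr].sum()
        e0 = len(gr) - e1
        o1 = y[gr].sum()
        o0 = len(gr) - o1
        if e1 <= 0 or e0 <= 0:
            # degenerate expectation; only a zero observed-expected gap is
            # consistent, anything else contributes infinitely -> collapse
            if abs(o1 - e1) > 1e-9:
                stat = np.inf
            continue
        stat += (o1 - e1) ** 2 / e1 + (o0 - e0) ** 2 / e0
        used += 1
    df = max(used - 2, 1)
    pval = float(stats.chi2.sf(stat, df)) if np.isfinite(stat) else 0.0
    return float(stat), pval


# ---------------------------------------------------------------------------
# probability-level logistic fusion
# ---------------------------------------------------------------------------


@dataclass
class FusionResults:
    """Fitted fusion coefficients, decision threshold and diagnostics."""

    intercept: float
    coefficients: np.ndarray
    threshold: float
    penalized: bool
    train_scores: np.ndarray
    train_labels: np.ndarray

    def predict(self, p_ct, p_pet) -> np.ndarray:
        X = np.column_stack([np.asarray(p_ct, float), np.asarray(p_pet, float)])
        eta = self.intercept + X @ self.coefficients
        return 1.0 / (1.0 + np.exp(-eta))

    def summary(self) -> str:
        lines = [
            "Probability-level logistic fusion",
            f"  intercept:  {self.intercept:+.4f}",
            f"  beta(CT):   {self.coefficients[0]:+.4f}",
            f"  beta(PET):  {self.coefficients[1]:+.4f}",
            f"  threshold:  {self.threshold:.4f} (Youden's J on training ROC)",
        ]
        if self.penalized:
            lines.append("  note: separation detected; L2-penalized fit used")
        return "\n".join(lines)


class ProbabilityFusion:
    """Maximum-likelihood logistic model on two probability streams."""

    def __init__(self, p_ct, p_pet, labels):
        self.p_ct = np.asarray(p_ct, dtype=float)
        self.p_pet = np.asarray(p_pet, dtype=float)
        self.labels = _check_binary(labels)
        if not (len(self.p_ct) == len(self.p_pet) == len(self.labels)):
            raise ValueError("probability streams and labels must align")

    def fit(self) -> FusionResults:
        import statsmodels.api as sm

        X = sm.add_constant(np.column_stack([self.p_ct, self.p_pet]))
        penalized = False
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("error")
                res = sm.Logit(self.labels, X).fit(disp=0)
            params = res.params
            if not np.all(np.isfinite(params)) or np.abs(params).max() > 1e3:
                raise RuntimeError("separation suspected")
        except Exception:
            # perfect separation: fall back to a penalized (L2) fit
            from sklearn.linear_model import LogisticRegression

            penalized = True
            lr = LogisticRegression(C=1.0, solver="lbfgs").fit(
                np.column_stack([self.p_ct, self.p_pet]), self.labels)
            params = np.concatenate([lr.intercept_, lr.coef_.ravel()])
        intercept, coefs = float(params[0]), np.asarray(params[1:], dtype=float)
        eta = intercept + np.column_stack([self.p_ct, self.p_pet]) @ coefs
        fused = 1.0 / (1.0 + np.exp(-eta))
        thr = youden_threshold(fused, self.labels)
        return FusionResults(intercept, coefs, thr, penalized, fused, self.labels)


def fit_fusion(p_ct, p_pet, labels) -> FusionResults:
    """Convenience wrapper: fit :class:`ProbabilityFusion` and return results."""
    return ProbabilityFusion(p_ct, p_pet, labels).fit()


# ---------------------------------------------------------------------------
# cohort evaluation report
# ---------------------------------------------------------------------------


@dataclass
class EvalReport:
    """Discrimination and calibration metrics of one model on one cohort."""

    auc: float
    auc_ci: tuple[float, float]
    accuracy: float
    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    confusion: dict
    hl_stat: float
    hl_p: float
    n: int

    def as_dict(self) -> dict:
        return {
            "auc": self.auc, "auc_ci_low": self.auc_ci[0],
            "auc_ci_high": self.auc_ci[1], "accuracy": self.accuracy,
            "sensitivity": self.sensitivity, "specificity": self.specificity,
            "ppv": self.ppv, "npv": self.npv, "hl_stat": self.hl_stat,
            "hl_p": self.hl_p, "n": self.n,
        }

    def summary(self) -> str:
        lo, hi = self.auc_ci
        return (
            f"n={self.n}  AUC {self.auc:.3f} (95% CI {lo:.3f}-{hi:.3f})  "
            f"acc {self.accuracy:.3f}  sens {self.sensitivity:.3f}  "
            f"spec {self.specificity:.3f}  PPV {self.ppv:.3f}  "
            f"NPV {self.npv:.3f}  HL p={self.hl_p:.3f}"
        )


def evaluate(scores, labels, threshold: float, hl_groups: int = 10) -> EvalReport:
    """Full per-cohort report: AUC/CI, 2x2 metrics at ``threshold``, calibration."""
    y = _check_binary(labels)
    s = np.asarray(scores, dtype=float)
    auc, lo, hi = roc_auc_ci(s, y)
    m = threshold_metrics(s, y, threshold)
    try:
        hl_stat, hl_p = hosmer_lemeshow(s, y, hl_groups)
    except ValueError:
        hl_stat, hl_p = float("nan"), float("nan")
    return EvalReport(auc, (lo, hi), m["accuracy"], m["sensitivity"],
                      m["specificity"], m["ppv"], m["npv"],
                      {k: m[k] for k in ("tp", "fp", "fn", "tn")},
                      hl_stat, hl_p, len(y))
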