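"""Diagnostic-group analyses on the consonants-in-noise score.

A linear discriminant on the single score separates externally diagnosed
learning-disability (LD) children from controls, reported with the
standard DFA statistics (resubstitution confusion matrix, Wilks lambda,
its chi-square approximation, and a one-way F on the group means).  A
threshold-sweep ROC characterizes the score as a screening instrument;
by convention the positive class is 'control' — the score is best at
clearing children as unlikely to be reading-impaired.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import roc_curve as _roc_curve


@dataclass
class GroupData:
    """Per-child score plus binary diagnostic label."""

    scores: np.ndarray
    labels: np.ndarray   # e.g. "LD" / "control"

    def __post_init__(self):
        self.scores = np.asarray(self.scores, dtype=float)
        self.labels = np.asarray(self.labels)
        if self.scores.shape != self.labels.shape:
            raise ValueError("scores and labels must align")
        uniq = np.unique(self.labels)
        if uniq.size != 2:
            raise ValueError(f"exactly two groups required, got {list(uniq)}")


@dataclass
class DFAResult:
    groups: tuple
    group_means: dict
    threshold: float
    confusion: dict            # (true, predicted) -> count
    percent_correct: float
    percent_correct_equal_priors: float
    wilks_lambda: float
    chi2: float
    chi2_dof: int
    chi2_p: float
    f_stat: float
    f_dof: tuple
    f_p: float
    n: int
    degenerate: bool = False


@dataclass
class ROCResult:
    fpr: np.ndarray            # 1 - specificity
    tpr: np.ndarray            # sensitivity
    thresholds: np.ndarray
    auc: float
    ci95: tuple
    p_value: float             # vs. AUC = 0.5 (Hanley-McNeil SE)
    positive_class: str
    degenerate: bool = False


def _threshold(mu_a: float, mu_b: float, pooled_var: float,
               log_prior_ratio: float) -> float:
    """Decision cut of the 1-D equal-variance linear discriminant.

    ``log_prior_ratio`` is ln(prior_a / prior_b); the cut shifts away
    from the more frequent group's mean, enlarging its decision region.
    """
    mid = 0.5 * (mu_a + mu_b)
    if mu_a == mu_b:
        return mid
    return mid - pooled_var * log_prior_ratio / (mu_a - mu_b)


def discriminant_classify(data: GroupData, priors: str = "observed") -> DFAResult:
    """Linear discriminant analysis of group membership from the score.

    With one predictor this reduces to a threshold rule: the pooled-
    variance cut between the group means, shifted by the log prior ratio
    (observed class frequencies by default; ``priors='equal'`` removes
    the shift).  Accuracy is resubstitution (the paper-style reporting
    convention), alongside Wilks lambda, its chi-square approximation,
    and the one-way F test on scores.
    """
    x, lab = data.scores, data.labels
    g = np.unique(lab)
    a, b = (x[lab == g[0]], x[lab == g[1]])
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least 2 children per group")
    n = x.size
    mu = {g[0]: float(a.mean()), g[1]: float(b.mean())}
    ss_within = float(((a - a.mean()) ** 2).sum() + ((b - b.mean()) ** 2).sum())
    ss_total = float(((x - x.mean()) ** 2).sum())
    degenerate = ss_within == 0.0 and mu[g[0]] == mu[g[1]]

    pooled_var = ss_within / (n - 2) if n > 2 else 0.0
    if priors == "observed":
        log_ratio = float(np.log(a.size / b.size))
    elif priors == "equal":
        log_ratio = 0.0
    else:
        raise ValueError("priors must be 'observed' or 'equal'")

    def classify(cut):
        # the group with the larger mean claims scores above the cut
        hi = g[0] if mu[g[0]] >= mu[g[1]] else g[1]
        lo = g[1] if hi == g[0] else g[0]
        return np.where(x > cut, hi, lo)

    def accuracy(cut):
        pred = classify(cut)
        conf = {(t, p): int(np.sum((lab == t) & (pred == p)))
                for t in g for p in g}
        pct = 100.0 * np.trace(np.array([[conf[(t, p)] for p in g]
                                         for t in g])) / n
        return conf, pct

    cut_obs = _threshold(mu[g[0]], mu[g[1]], pooled_var,
                         log_ratio) if not degenerate else float(x.mean())
    cut_eq = _threshold(mu[g[0]], mu[g[1]], pooled_var, 0.0) \
        if not degenerate else float(x.mean())
    conf, pct = accuracy(cut_obs)
    _, pct_eq = accuracy(cut_eq)

    lam = ss_within / ss_total if ss_total > 0 else 1.0
    p_vars, n_groups = 1, 2
    dof = p_vars * (n_groups - 1)
    chi2 = (-(n - 1 - (p_vars + n_groups) / 2.0) * np.log(lam)
            if lam > 0 else np.inf)
    chi2_p = float(stats.chi2.sf(chi2, dof))
    f_stat, f_p = stats.f_oneway(a, b)

    return DFAResult(
        groups=tuple(g), group_means=mu, threshold=float(cut_obs),
        confusion=conf, percent_correct=float(pct),
        percent_correct_equal_priors=float(pct_eq),
        wilks_lambda=float(lam), chi2=float(chi2), chi2_dof=dof,
        chi2_p=chi2_p, f_stat=float(f_stat), f_dof=(1, n - 2),
        f_p=float(f_p), n=n, degenerate=degenerate,
    )


def _hanley_mcneil_se(a: float, n1: int, n2: int) -> float:
    q1 = a / (2.0 - a)
    q2 = 2.0 * a * a / (1.0 + a)
    var = (a * (1 - a) + (n1 - 1) * (q1 - a * a)
           + (n2 - 1) * (q2 - a * a)) / (n1 * n2)
    return float(np.sqrt(max(var, 0.0)))


def roc_analysis(data: GroupData, positive: str = "control") -> ROCResult:
    """Empirical ROC of the score for detecting the positive class.

    The curve is the full threshold sweep over observed scores; AUC by
    the trapezoid rule (equal to the Mann-Whitney U statistic scaled by
    n1*n2).  The 95% CI and the p-value against AUC = 0.5 use the
    Hanley-McNeil standard error.
    """
    if positive not in data.labels:
        raise ValueError(f"positive class {positive!r} not present")
    y = (data.labels == positive).astype(int)
    if np.unique(data.scores).size == 1:
        k = data.scores.size
        return ROCResult(fpr=np.array([0.0, 1.0]), tpr=np.array([0.0, 1.0]),
                         thresholds=np.array([np.inf, data.scores[0]]),
                         auc=0.5, ci95=(0.0, 1.0), p_value=1.0,
                         positive_class=positive, degenerate=True)
    fpr, tpr, thr = _roc_curve(y, data.scores)
    a = float(_trapezoid_auc(fpr, tpr))
    n1 = int(y.sum())
    n2 = int(y.size - n1)
    se = _hanley_mcneil_se(a, n1, n2)
    if se == 0.0:
        ci, p = (a, a), 0.0
    else:
        ci = (max(0.0, a - 1.959964 * se), min(1.0, a + 1.959964 * se))
        p = float(2.0 * stats.norm.sf(abs(a - 0.5) / se))
    return ROCResult(fpr=fpr, tpr=tpr, thresholds=thr, auc=a, ci95=ci,
                     p_value=p, positive_class=positive)
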