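"""Agreement and discrimination statistics for FAZ measurements.

Bland–Altman analysis quantifies agreement between two measurement
methods through the paired differences: bias (mean difference), its 95%
confidence interval, and the limits of agreement bias +/- 1.96 SD.
Discrimination of two groups (e.g. normal vs glaucomatous eyes) from a
single FAZ parameter uses a univariate logistic regression; because the
logistic score is monotone in the feature, the resulting ROC/AUC equals
the Mann–Whitney rank AUC of the raw feature (up to sign).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm

__all__ = ["AgreementReport", "RocReport", "bland_altman", "pearson_r",
           "auc_logistic"]


@dataclass
class AgreementReport:
    bias: float
    sd_diff: float
    loa_low: float
    loa_high: float
    ci95_low: float
    ci95_high: float
    n: int

    def to_dict(self):
        return self.__dict__.copy()


@dataclass
class RocReport:
    auc: float
    se_auc: float
    fpr: np.ndarray
    tpr: np.ndarray
    intercept: float
    slope: float
    n_pos: int
    n_neg: int

    @property
    def ci95(self):
        return (self.auc - 1.96 * self.se_auc, self.auc + 1.96 * self.se_auc)

    def to_dict(self):
        return {"auc": self.auc, "se_auc": self.se_auc,
                "ci95_low": self.ci95[0], "ci95_high": self.ci95[1],
                "intercept": self.intercept, "slope": self.slope,
                "n_pos": self.n_pos, "n_neg": self.n_neg,
                "fpr": list(map(float, self.fpr)),
                "tpr": list(map(float, self.tpr))}


def bland_altman(a, b) -> AgreementReport:
    """Bland–Altman agreement between paired measurements ``a`` and ``b``."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("a and b must be 1-D arrays of equal length")
    n = len(a)
    if n < 2:
        raise ValueError("need at least two pairs")
    d = a - b
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    half = 1.96 * sd
    ci = 1.96 * sd / np.sqrt(n)
    return AgreementReport(bias=bias, sd_diff=sd,
                           loa_low=bias - half, loa_high=bias + half,
                           ci95_low=bias - ci, ci95_high=bias + ci, n=n)


def pearson_r(a, b) -> float:
    """Product-moment correlation coefficient."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("a and b must be 1-D arrays of equal length")
    if len(a) < 3:
        raise ValueError("need at least three pairs")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("zero variance input")
    am, bm = a - a.mean(), b - b.mean()
    return float((am @ bm) / np.sqrt((am @ am) * (bm @ bm)))


def _hanley_mcneil_se(auc, n_pos, n_neg):
    q1 = auc / (2.0 - auc)
    q2 = 2.0 * auc * auc / (1.0 + auc)
    var = (auc * (1 - auc) + (n_pos - 1) * (q1 - auc * auc)
           + (n_neg - 1) * (q2 - auc * auc)) / (n_pos * n_neg)
    return float(np.sqrt(max(var, 0.0)))


def _roc_points(scores, y):
    """Threshold sweep over the score; ties collapse onto one point."""
    order = np.argsort(-scores, kind="stable")
    s, yy = scores[order], y[order]
    n_pos, n_neg = int(yy.sum()), int(len(yy) - yy.sum())
    tps = np.cumsum(yy)
    fps = np.cumsum(1 - yy)
    # keep the last index of each distinct score (all ties grouped)
    distinct = np.nonzero(np.diff(s))[0]
    idx = np.concatenate([distinct, [len(s) - 1]])
    tpr = np.concatenate([[0.0], tps[idx] / n_pos])
    fpr = np.concatenate([[0.0], fps[idx] / n_neg])
    return fpr, tpr


def auc_logistic(feature, labels, positive_label=None) -> RocReport:
    """ROC/AUC for one scalar feature via univariate logistic regression.

    The logistic model is fitted by iteratively reweighted least squares
    (tolerance 1e-8, at most 100 iterations) and its intercept/slope are
    reported.  Because the logistic score is a monotone transform of the
    single feature, the ROC depends only on the feature ordering; it is
    computed in the raw-feature orientation (larger feature values score
    as more likely positive), so the AUC equals the Mann–Whitney rank
    AUC of the feature, a label flip maps AUC to 1 - AUC, and an inverse
    association shows up as AUC < 0.5.  AUC is the trapezoidal area; its
    standard error follows Hanley & McNeil.  Under complete separation
    the ML slope diverges but the ROC remains well-defined.
    """
    x = np.asarray(feature, dtype=float)
    labels = np.asarray(labels)
    if x.ndim != 1 or labels.shape != x.shape:
        raise ValueError("feature and labels must be 1-D of equal length")
    classes = np.unique(labels)
    if len(classes) != 2:
        raise ValueError(f"need exactly two classes, got {list(classes)}")
    if positive_label is None:
        positive_label = classes[-1]
    y = (labels == positive_label).astype(float)
    n_pos, n_neg = int(y.sum()), int(len(y) - y.sum())
    if n_pos < 2 or n_neg < 2:
        raise ValueError("need at least two subjects per class")

    X = sm.add_constant(x)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = sm.GLM(y, X, family=sm.families.Binomial()).fit(
            maxiter=100, tol=1e-8)
    intercept, slope = map(float, res.params)
    fpr, tpr = _roc_points(x, y)
    auc = float(np.trapezoid(tpr, fpr))
    return RocReport(auc=auc, se_auc=_hanley_mcneil_se(auc, n_pos, n_neg),
                     fpr=fpr, tpr=tpr, intercept=intercept, slope=slope,
                     n_pos=n_pos, n_neg=n_neg)


def plot_bland_altman(report: AgreementReport, a, b, path):
    """Write a Bland–Altman scatter plot to ``path``."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    mean = (a + b) / 2
    diff = a - b
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(mean, diff, s=12, alpha=0.7)
    for yv, style in ((report.bias, "-"), (report.loa_low, "--"),
                      (report.loa_high, "--")):
        ax.axhline(yv, color="crimson", linestyle=style, linewidth=1)
    ax.set_xlabel("mean of methods")
    ax.set_ylabel("difference")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_roc(report: RocReport, path):
    """Write the ROC curve to ``path``."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    fig, ax = plt.subplots(figsize=(4.5, 4.5))
    ax.plot(report.fpr, report.tpr, label=f"AUC = {report.auc:.3f}")
    ax.plot([0, 1], [0, 1], "k:", linewidth=1)
    ax.set_xlabel("false positive rate")
    ax.set_ylabel("true positive rate")
    ax.legend(loc="lower right")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
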