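"""ROC evaluation and agreement statistics.

The evaluation protocol for the subregion classifiers:

* AUC with a DeLong variance estimate and a normal-approximation 95% CI;
* paired DeLong tests between correlated AUCs (same patients, two models);
* operating point by the Youden index (max sensitivity + specificity - 1),
  chosen on training scores and carried to validation;
* Lilliefors-corrected Kolmogorov-Smirnov normality screen deciding
  whether a feature is summarized as mean +/- SD or median +/- IQR;
* univariate logistic AUC per feature;
* ICC(2,1) — two-way random effects, absolute agreement, single
  measures — for inter-reader feature reproducibility.

The DeLong machinery follows the structural-components decomposition of
the Mann-Whitney AUC: with positives X_1..X_m and negatives Y_1..Y_n,
V10_i = mean_j psi(X_i, Y_j) and V01_j = mean_i psi(X_i, Y_j) where psi
scores 1 / 0.5 / 0 for a win / tie / loss; then
Var(AUC) = S10/m + S01/n with S the sample (co)variances of the
components, and paired AUC differences are z-tested with the matching
covariance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from statsmodels.stats.diagnostic import lilliefors

__all__ = [
    "ROCResult",
    "auc_delong",
    "delong_components",
    "delong_test",
    "youden_metrics",
    "ks_normality",
    "univariate_auc",
    "icc_agreement",
]


@dataclass
class ROCResult:
    auc: float
    ci_low: float
    ci_high: float
    se: float
    sensitivity: float | None = None
    specificity: float | None = None
    accuracy: float | None = None
    threshold: float | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.auc <= 1.0):
            raise ValueError("AUC must lie in [0, 1]")


def _check_binary(labels: np.ndarray) -> np.ndarray:
    y = np.asarray(labels)
    classes = np.unique(y)
    if classes.size != 2:
        raise ValueError("labels must contain exactly two classes")
    return y == classes.max()


def delong_components(scores: np.ndarray, labels: np.ndarray):
    """AUC and its DeLong structural components (V10 for positives, V01)."""
    y = _check_binary(labels)
    s = np.asarray(scores, dtype=np.float64)
    x, yneg = s[y], s[~y]
    if x.size == 0 or yneg.size == 0:
        raise ValueError("both classes must be present")
    psi = (x[:, None] > yneg[None, :]).astype(np.float64)
    psi += 0.5 * (x[:, None] == yneg[None, :])
    v10 = psi.mean(axis=1)
    v01 = psi.mean(axis=0)
    return float(v10.mean()), v10, v01


def auc_delong(scores, labels) -> ROCResult:
    """AUC with DeLong SE and 95% normal CI clipped to [0, 1]."""
    auc, v10, v01 = delong_components(scores, labels)
    m, n = v10.size, v01.size
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    se = float(np.sqrt(s10 / m + s01 / n))
    lo = float(np.clip(auc - 1.959963984540054 * se, 0.0, 1.0))
    hi = float(np.clip(auc + 1.959963984540054 * se, 0.0, 1.0))
    return ROCResult(auc=auc, ci_low=lo, ci_high=hi, se=se)


def delong_test(scores_a, scores_b, labels) -> float:
    """Two-sided paired DeLong test for a difference between two AUCs.

    Scores must be paired on the same patients.  Identical score vectors
    (or a degenerate zero-variance difference) give p = 1.
    """
    a = np.asarray(scores_a, dtype=np.float64)
    b = np.asarray(scores_b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError("paired score vectors must have equal length")
    auc_a, v10a, v01a = delong_components(a, labels)
    auc_b, v10b, v01b = delong_components(b, labels)
    m, n = v10a.size, v01a.size
    if m < 2 or n < 2:
        raise ValueError("need at least two patients per class")
    s10 = np.cov(v10a, v10b)  # 2x2
    s01 = np.cov(v01a, v01b)
    var_diff = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m \
        + (s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]) / n
    diff = auc_a - auc_b
    if var_diff <= 0:
        return 1.0 if diff == 0 else 0.0
    z = diff / np.sqrt(var_diff)
    return float(2.0 * stats.norm.sf(abs(z)))


def roc_points(scores, labels) -> dict[str, np.ndarray]:
    """ROC curve coordinates (FPR, TPR, thresholds) for plotting/export."""
    from sklearn.metrics import roc_curve

    y = _check_binary(labels)
    fpr, tpr, thr = roc_curve(y.astype(int), np.asarray(scores, dtype=np.float64))
    return {"fpr": fpr, "tpr": tpr, "threshold": thr}


def youden_metrics(scores, labels) -> dict[str, float]:
    """Operating point maximizing the Youden index.

    A case is called positive when its score is >= the threshold;
    candidate thresholds are the observed scores, ties resolving to the
    lowest threshold.  With all scores equal this degenerates to calling
    everything positive (sensitivity 1, specificity 0).
    """
    y = _check_binary(labels)
    s = np.asarray(scores, dtype=np.float64)
    best = None
    for thr in np.sort(np.unique(s)):
        pred = s >= thr
        sens = float((pred & y).sum() / y.sum())
        spec = float((~pred & ~y).sum() / (~y).sum())
        j = sens + spec - 1.0
        if best is None or j > best[0] + 1e-12:
            best = (j, thr, sens, spec)
    _, thr, sens, spec = best
    pred = s >= thr
    acc = float((pred == y).mean())
    return {"sensitivity": sens, "specificity": spec, "accuracy": acc,
            "threshold": float(thr)}


def metrics_at_threshold(scores, labels, threshold: float) -> dict[str, float]:
    """Sensitivity/specificity/accuracy at a fixed (training-derived) threshold."""
    y = _check_binary(labels)
    s = np.asarray(scores, dtype=np.float64)
    pred = s >= threshold
    return {
        "sensitivity": float((pred & y).sum() / y.sum()),
        "specificity": float((~pred & ~y).sum() / (~y).sum()),
        "accuracy": float((pred == y).mean()),
        "threshold": float(threshold),
    }


def ks_normality(values, alpha: float = 0.05) -> tuple[float, str]:
    """Lilliefors-corrected KS normality screen.

    Returns ``(p, mode)`` where mode is ``"mean±SD"`` when normality is
    not rejected at ``alpha`` and ``"median±IQR"`` otherwise.  A constant
    sample is non-normal by convention.
    """
    v = np.asarray(values, dtype=np.float64)
    if v.size < 4:
        raise ValueError("need at least 4 observations")
    if v.std() == 0:
        return 0.0, "median±IQR"
    _, p = lilliefors(v, dist="norm")
    return float(p), ("mean±SD" if p >= alpha else "median±IQR")


def univariate_auc(feature, labels) -> dict[str, float]:
    """Single-feature logistic fit: AUC of fitted probabilities + Wald p.

    The logistic slope absorbs the feature's orientation, so the AUC is
    direction-free.  Under perfect separation the Wald p-value is
    unreliable and reported as NaN with ``wald_reliable = 0``.
    """
    import statsmodels.api as sm

    y = _check_binary(labels).astype(float)
    x = np.asarray(feature, dtype=np.float64)
    X = sm.add_constant((x - x.mean()) / (x.std() if x.std() > 0 else 1.0))
    reliable = 1.0
    try:
        with np.errstate(all="ignore"):
            fit = sm.Logit(y, X).fit(disp=0, maxiter=200)
        p_wald = float(fit.pvalues[1])
        probs = np.asarray(fit.predict(X))
        if not np.isfinite(p_wald) or fit.bse[1] > 1e3:
            reliable = 0.0
            p_wald = np.nan
    except Exception:  # perfect separation and friends
        reliable = 0.0
        p_wald = np.nan
        # orientation from the sign of the point-biserial association
        sign = 1.0 if np.corrcoef(x, y)[0, 1] >= 0 else -1.0
        probs = sign * x
    auc, _, _ = delong_components(probs, y)
    return {"auc": float(auc), "p_wald": p_wald, "wald_reliable": reliable}


def icc_agreement(readings_a, readings_b) -> float:
    """ICC(2,1): two-way random effects, absolute agreement, single measures.

    Computed from the two-way ANOVA decomposition over n subjects and
    k = 2 raters:

        ICC = (MSR - MSE) / (MSR + (k-1) MSE + k (MSC - MSE) / n)
    """
    a = np.asarray(readings_a, dtype=np.float64)
    b = np.asarray(readings_b, dtype=np.float64)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("readings must be paired 1D arrays")
    n = a.size
    if n < 3:
        raise ValueError("need at least 3 subjects")
    data = np.stack([a, b], axis=1)  # n x k
    k = 2
    grand = data.mean()
    row_means = data.mean(axis=1)
    col_means = data.mean(axis=0)
    ssr = k * ((row_means - grand) ** 2).sum()
    ssc = n * ((col_means - grand) ** 2).sum()
    sst = ((data - grand) ** 2).sum()
    sse = sst - ssr - ssc
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    if denom == 0:
        return 1.0
    return float((msr - mse) / denom)
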