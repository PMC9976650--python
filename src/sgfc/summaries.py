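"""Network-level and node-level summaries of FC and sgFC maps.

Provides the intrinsic-network decomposition (within- and between-
network means of positive-valued connectivity), positive node
strengths, the exponential strength-vs-strength fit, and the residual
vs hierarchy correlation used to localize unexpectedly strong
polysynaptic connectivity along the cortical gradient.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "NetworkSummary",
    "ExpFit",
    "positive_strength",
    "within_between_means",
    "summary_ratios",
    "fit_exponential",
    "residual_gradient_correlation",
]

log = logging.getLogger(__name__)


@dataclass
class NetworkSummary:
    """Within-network means (per network) and the cross-network mean of
    positive-valued connectivity, with contributing entry counts."""

    within_mean: dict
    within_count: dict
    between_mean: float
    between_count: int


@dataclass
class ExpFit:
    """y = a * exp(b * x) least-squares fit (log space), with residuals
    and R^2 reported in the original y space."""

    a: float
    b: float
    r_squared: float
    residuals: np.ndarray
    n_excluded: int = 0

    def predict(self, x: np.ndarray) -> np.ndarray:
        return self.a * np.exp(self.b * np.asarray(x, float))


def positive_strength(m: np.ndarray, mask: np.ndarray | None = None) -> np.ndarray:
    """Per-node sum of positive defined entries of a symmetric matrix.

    ``mask`` marks defined entries; by default every finite off-
    diagonal entry counts.  Undefined and negative entries contribute
    nothing.
    """
    m = np.asarray(m, float)
    n = m.shape[0]
    defined = np.isfinite(m)
    if mask is not None:
        defined = defined & np.asarray(mask, bool)
    defined = defined & ~np.eye(n, dtype=bool)
    contrib = np.where(defined & (m > 0), m, 0.0)
    return contrib.sum(axis=1)


def within_between_means(
    m: np.ndarray, labels: np.ndarray, mask: np.ndarray | None = None
) -> NetworkSummary:
    """Mean positive-valued connectivity within each network and
    between networks, over defined off-diagonal entries only."""
    m = np.asarray(m, float)
    n = m.shape[0]
    labels = np.asarray(labels)
    if labels.shape[0] != n:
        raise ValueError("labels length mismatch")
    uniq = sorted(set(labels.tolist()), key=str)
    if len(uniq) < 1:
        raise ValueError("need at least one network label")
    defined = np.isfinite(m)
    if mask is not None:
        defined = defined & np.asarray(mask, bool)
    iu = np.triu_indices(n, k=1)
    use = defined[iu] & (m[iu] > 0)
    same = labels[iu[0]] == labels[iu[1]]

    within_mean: dict = {}
    within_count: dict = {}
    for lab in uniq:
        sel = use & same & (labels[iu[0]] == lab)
        cnt = int(sel.sum())
        within_count[lab] = cnt
        if cnt == 0:
            log.warning("network %r has no positive defined within entries", lab)
            within_mean[lab] = float("nan")
        else:
            within_mean[lab] = float(m[iu][sel].mean())
    betw_sel = use & ~same
    between_count = int(betw_sel.sum())
    if between_count == 0:
        log.warning("no positive defined between-network entries")
        between_mean = float("nan")
    else:
        between_mean = float(m[iu][betw_sel].mean())
    return NetworkSummary(within_mean, within_count, between_mean, between_count)


def summary_ratios(num: NetworkSummary, den: NetworkSummary) -> dict:
    """Paired ratio table (e.g., sgFC summary over baseline summary)."""
    out = {"between": num.between_mean / den.between_mean}
    for lab in num.within_mean:
        out[lab] = num.within_mean[lab] / den.within_mean.get(lab, float("nan"))
    return out


def fit_exponential(x: np.ndarray, y: np.ndarray) -> ExpFit:
    """Fit the exponential family y = a exp(b x) by least squares on
    log y over the strictly positive y values.

    Nodes with y <= 0 (or non-finite) are excluded from the fit and
    counted in ``n_excluded``; residuals y - a exp(b x) are reported
    for every input point.  R^2 is computed in the original y space
    over the fitted points.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    usable = np.isfinite(x) & np.isfinite(y) & (y > 0)
    n_excluded = int(x.size - usable.sum())
    if usable.sum() < 3:
        raise ValueError("need at least 3 points with positive y to fit")
    b, log_a = np.polyfit(x[usable], np.log(y[usable]), 1)
    a = float(np.exp(log_a))
    pred = a * np.exp(b * x)
    residuals = y - pred
    yy = y[usable]
    ss_res = float(((yy - pred[usable]) ** 2).sum())
    ss_tot = float(((yy - yy.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")
    return ExpFit(a=a, b=float(b), r_squared=r2, residuals=residuals, n_excluded=n_excluded)


def residual_gradient_correlation(
    residuals: np.ndarray, gradient: np.ndarray
) -> float:
    """Pearson correlation between strength residuals and a hierarchy map."""
    residuals = np.asarray(residuals, float)
    gradient = np.asarray(gradient, float)
    if residuals.shape != gradient.shape:
        raise ValueError("length mismatch")
    if np.std(residuals) == 0 or np.std(gradient) == 0:
        raise ValueError("zero variance input")
    return float(stats.pearsonr(residuals, gradient)[0])
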