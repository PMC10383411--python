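"""Soil-line extraction by logistic classification of bare-soil pixels.

Bare-soil reflectance in the red and NIR bands falls on a linear locus (the
"soil line"); pixels contaminated by vegetation residue (mixels) sit above
it, with elevated NIR.  A four-band logistic model

    p = 1 / (1 + exp(-(alpha + sum_i beta_i * X_i)))

with X = (green, red, Red edge, NIR) DN separates clean soil-line pixels
(p >= 0.5) from mixels, after which the soil line itself is fitted by
ordinary least squares of NIR on red over the clean class.

The maximum-likelihood fit runs iteratively reweighted least squares (IRLS)
on standardized predictors and reports coefficients on the original DN
scale.  Complete separation — the expected good case for two distinct pixel
clusters — is detected by coefficient-norm divergence and reported rather
than treated as failure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "LogisticModel",
    "SoilLine",
    "fit_logistic",
    "classify_pixels",
    "fit_soil_line",
    "initial_labels_from_soil_line",
    "estimate_mixel_fraction",
]

_IRLS_TOL = 1e-8
_IRLS_MAX_ITER = 100
_RIDGE = 1e-6
_SEPARATION_NORM = 30.0  # |coef| on standardized scale beyond which the fit
                         # has effectively reached complete separation


@dataclass
class LogisticModel:
    """Four-band logistic classifier for soil-line membership."""

    alpha: float
    betas: np.ndarray            # one slope per band, original DN scale
    converged: bool
    n_iter: int
    separated: bool = False
    log_likelihood: float = float("nan")
    ll_path: list = field(default_factory=list, repr=False)

    def linear_predictor(self, x: np.ndarray) -> np.ndarray:
        return self.alpha + np.asarray(x, dtype=float) @ self.betas

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        eta = np.clip(self.linear_predictor(x), -700, 700)
        return 1.0 / (1.0 + np.exp(-eta))


@dataclass
class SoilLine:
    """NIR = intercept + slope * red over clean bare-soil pixels."""

    intercept: float
    slope: float
    rmse: float
    n: int

    def predict(self, red):
        return self.intercept + self.slope * np.asarray(red, dtype=float)


def _log_likelihood(eta: np.ndarray, y: np.ndarray) -> float:
    # numerically stable Bernoulli log-likelihood
    return float(np.sum(y * eta - np.logaddexp(0.0, eta)))


def fit_logistic(pixels: np.ndarray, labels: np.ndarray) -> LogisticModel:
    """Maximum-likelihood logistic fit by IRLS.

    ``pixels`` is (n, 4) band DN rows; ``labels`` is 0/1 (1 = clean soil
    line).  Predictors are standardized internally for conditioning; the
    returned coefficients are on the original DN scale.  Requires both
    classes and at least 5 rows.
    """
    x = np.asarray(pixels, dtype=float)
    y = np.asarray(labels, dtype=float).ravel()
    if x.ndim != 2:
        raise ValueError("pixels must be a 2-D array of band rows")
    n, k = x.shape
    if n < 5:
        raise ValueError("logistic fit needs at least 5 pixels")
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")

    mu = x.mean(axis=0)
    sd = x.std(axis=0)
    sd[sd == 0] = 1.0
    z = (x - mu) / sd
    design = np.column_stack([np.ones(n), z])

    coef = np.zeros(k + 1)
    converged = False
    separated = False
    ll_path: list[float] = []
    n_iter = 0
    for n_iter in range(1, _IRLS_MAX_ITER + 1):
        eta = np.clip(design @ coef, -30, 30)
        p = 1.0 / (1.0 + np.exp(-eta))
        w = p * (1.0 - p)
        ll_path.append(_log_likelihood(design @ coef, y))
        # weighted normal equations with a ridge jitter against singularity
        wd = design * w[:, None]
        hess = design.T @ wd + _RIDGE * np.eye(k + 1)
        grad = design.T @ (y - p)
        step = np.linalg.solve(hess, grad)
        coef = coef + step
        if np.linalg.norm(coef[1:]) > _SEPARATION_NORM:
            separated = True
            break
        if np.max(np.abs(step)) < _IRLS_TOL:
            converged = True
            break
    ll_path.append(_log_likelihood(design @ coef, y))
    if not converged and ll_path[-1] > -1e-4:
        # deviance has effectively vanished: the classes are separable and
        # the MLE diverges; report the achieved boundary instead of failing
        separated = True

    betas = coef[1:] / sd
    alpha = coef[0] - float(mu @ betas)
    return LogisticModel(alpha=float(alpha), betas=betas,
                         converged=converged, n_iter=n_iter,
                         separated=separated,
                         log_likelihood=ll_path[-1], ll_path=ll_path)


def classify_pixels(model: LogisticModel, pixels: np.ndarray,
                    threshold: float = 0.5) -> tuple[np.ndarray, np.ndarray]:
    """Probabilities and hard labels (1 = soil line iff p >= threshold)."""
    p = model.predict_proba(np.asarray(pixels, dtype=float))
    return p, (p >= threshold).astype(int)


def fit_soil_line(red: np.ndarray, nir: np.ndarray) -> SoilLine:
    """OLS of NIR on red over clean pixels; needs >= 3 points."""
    red = np.asarray(red, dtype=float)
    nir = np.asarray(nir, dtype=float)
    if len(red) < 3:
        raise ValueError("soil line fit needs at least 3 clean pixels")
    if np.std(red) == 0:
        raise ValueError("red band is constant; soil line is undefined")
    fit = stats.linregress(red, nir)
    resid = nir - (fit.intercept + fit.slope * red)
    rmse = float(np.sqrt(np.mean(resid**2)))
    return SoilLine(intercept=float(fit.intercept), slope=float(fit.slope),
                    rmse=rmse, n=len(red))


def initial_labels_from_soil_line(pixels: np.ndarray,
                                  red_col: int = 1, nir_col: int = 3
                                  ) -> np.ndarray:
    """Provisional 0/1 labels for logistic training when none are supplied.

    A provisional soil line is fitted to *all* pixels; their NIR residuals
    are split by a two-means partition (the 1-D k-means optimum found by
    scanning the sorted residuals), and the low-residual group — the pixels
    hugging the line — becomes the clean class.
    """
    x = np.asarray(pixels, dtype=float)
    provisional = fit_soil_line(x[:, red_col], x[:, nir_col])
    resid = x[:, nir_col] - provisional.predict(x[:, red_col])
    order = np.argsort(resid)
    r = resid[order]
    n = len(r)
    # best split index minimises within-group sum of squares (exact 1-D 2-means)
    csum = np.cumsum(r)
    csum2 = np.cumsum(r**2)
    best_i, best_cost = 1, np.inf
    for i in range(1, n):
        left = csum2[i - 1] - csum[i - 1] ** 2 / i
        right = (csum2[-1] - csum2[i - 1]) - (csum[-1] - csum[i - 1]) ** 2 / (n - i)
        cost = left + right
        if cost < best_cost:
            best_cost, best_i = cost, i
    labels = np.zeros(n, dtype=int)
    labels[order[:best_i]] = 1  # low residual = clean soil line
    return labels


def estimate_mixel_fraction(pixels: np.ndarray,
                            labels: np.ndarray | None = None) -> dict:
    """Full pipeline: provisional labels (unless given), logistic refit,
    classification, and soil-line fit on the clean class.

    Returns the model, soil line, per-pixel probabilities/labels and the
    estimated mixel (contaminated) fraction.
    """
    x = np.asarray(pixels, dtype=float)
    if labels is None:
        labels = initial_labels_from_soil_line(x)
    model = fit_logistic(x, labels)
    p, pred = classify_pixels(model, x)
    clean = pred == 1
    line = fit_soil_line(x[clean, 1], x[clean, 3]) if clean.sum() >= 3 else None
    return {
        "model": model,
        "soil_line": line,
        "proba": p,
        "labels": pred,
        "mixel_fraction": float(1.0 - clean.mean()),
    }


def scatter_table(pixels: np.ndarray, labels: np.ndarray) -> pd.DataFrame:
    """Red/NIR scatter data with class labels, ready for plotting or CSV."""
    x = np.asarray(pixels, dtype=float)
    return pd.DataFrame({"red": x[:, 1], "nir": x[:, 3],
                         "label": np.asarray(labels, dtype=int)})
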