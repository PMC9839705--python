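"""Linear regression from latent features to chronological age.

The age model is the linear readout

    y_age = beta_1 z_1 + ... + beta_m z_m + alpha,

fit by least squares on the encoder's posterior means.  In single-VAE mode
the features are the n latent means of each image.  In parallel mode each
subject pair contributes n + k features: the k unique coordinates of each
branch plus one copy of the common half (the two common halves are
near-identical after training, so their elementwise mean is used; a
branch-A-only switch exists for sensitivity probes).

Evaluation mirrors forensic-odontology reporting: absolute errors in years
summarized per 10-year age group (10-19 ... 70-79) and overall, with the
median absolute error as the headline statistic alongside mean and
standard deviation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .phantom import DECADES
from .vae import TrainedVAE, _as_batch, _encode_fw
from .parallel import TrainedParallelVAE

__all__ = [
    "FeatureMatrix",
    "AgeRegressionModel",
    "extract_features",
    "fit_age_regression",
    "predict_age",
    "evaluate",
    "save_regression",
    "load_regression",
]


@dataclass
class FeatureMatrix:
    """Latent features, one row per image (single) or subject pair (parallel)."""

    X: np.ndarray
    column_origin: list[str]           # per-column tag
    mode: str                          # 'single' | 'parallel'

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 2 or self.X.shape[1] != len(self.column_origin):
            raise ValueError("X must be 2-D with one origin tag per column")

    @property
    def m(self) -> int:
        return self.X.shape[1]


@dataclass
class AgeRegressionModel:
    beta: np.ndarray
    alpha: float
    feature_layout: list[str]
    solver: str = "minnorm"
    ridge_lambda: float = 0.0

    def __post_init__(self) -> None:
        self.beta = np.asarray(self.beta, dtype=float).ravel()
        if self.beta.shape[0] != len(self.feature_layout):
            raise ValueError("beta length must match feature_layout")
        if not np.all(np.isfinite(self.beta)) or not np.isfinite(self.alpha):
            raise ValueError("regression parameters must be finite")


def _mu_batch(branch: TrainedVAE, images) -> np.ndarray:
    x = _as_batch(images, branch.config.image_side)
    mu, _, _ = _encode_fw(branch.params, branch.config, x)
    return mu


def extract_features(model, records, common: str = "mean") -> FeatureMatrix:
    """Posterior-mean latent features for a list of records.

    Single mode: ``records`` are images (2-D arrays); one row of n latent
    means per image.  Parallel mode: ``records`` are paired subject records;
    one row of n + k features per pair, ordered [unique_a, unique_b, common],
    where the common block is the mean of the two branches' common halves
    (``common='branch_a'`` takes branch A's copy instead).
    """
    if len(records) == 0:
        raise ValueError("no records to extract features from")
    if isinstance(model, TrainedParallelVAE):
        if not hasattr(records[0], "image_a"):
            raise ValueError("parallel mode expects paired subject records")
        k = model.k
        mua = _mu_batch(model.branch_a, [r.image_a for r in records])
        mub = _mu_batch(model.branch_b, [r.image_b for r in records])
        if common == "mean":
            zc = 0.5 * (mua[:, k:] + mub[:, k:])
        elif common == "branch_a":
            zc = mua[:, k:]
        else:
            raise ValueError(f"unknown common-feature rule {common!r}")
        X = np.hstack([mua[:, :k], mub[:, :k], zc])
        origin = (["unique_a"] * k) + (["unique_b"] * k) + (["common"] * k)
        return FeatureMatrix(X=X, column_origin=origin, mode="parallel")
    if isinstance(model, TrainedVAE):
        first = records[0]
        if not (isinstance(first, np.ndarray) and first.ndim == 2):
            raise ValueError("single mode expects a list of 2-D images")
        mu = _mu_batch(model, records)
        return FeatureMatrix(X=mu, column_origin=["latent"] * mu.shape[1],
                             mode="single")
    raise ValueError(f"unsupported model type {type(model).__name__}")


def fit_age_regression(X: FeatureMatrix, ages, solver: str = "minnorm",
                       ridge_lambda: float = 1.0) -> AgeRegressionModel:
    """Least-squares fit of age on latent features.

    ``minnorm`` (default) solves the centered normal equations by
    minimum-norm least squares, which stays well-defined when features
    outnumber samples; ``ridge`` adds an L2 penalty ``ridge_lambda``.
    """
    A = X.X
    y = np.asarray(ages, dtype=float).ravel()
    if A.shape[0] != y.shape[0] or A.shape[0] == 0 or A.shape[1] == 0:
        raise ValueError(f"degenerate design: X {A.shape}, ages {y.shape}")
    x_mean = A.mean(axis=0)
    y_mean = y.mean()
    Ac = A - x_mean
    yc = y - y_mean
    if solver == "minnorm":
        beta, *_ = np.linalg.lstsq(Ac, yc, rcond=None)
    elif solver == "ridge":
        from sklearn.linear_model import Ridge
        rr = Ridge(alpha=ridge_lambda, fit_intercept=False)
        rr.fit(Ac, yc)
        beta = rr.coef_
    else:
        raise ValueError(f"unknown solver {solver!r}")
    alpha = float(y_mean - x_mean @ beta)
    return AgeRegressionModel(beta=beta, alpha=alpha,
                              feature_layout=list(X.column_origin),
                              solver=solver,
                              ridge_lambda=ridge_lambda if solver == "ridge" else 0.0)


def predict_age(model: AgeRegressionModel, X: FeatureMatrix | np.ndarray) -> np.ndarray:
    """Raw linear predictions y_hat = X beta + alpha (no clipping)."""
    if isinstance(X, FeatureMatrix):
        if X.column_origin != model.feature_layout:
            raise ValueError("feature layout does not match the fitted model")
        A = X.X
    else:
        A = np.atleast_2d(np.asarray(X, dtype=float))
        if A.shape[1] != model.beta.shape[0]:
            raise ValueError(
                f"feature count {A.shape[1]} != model {model.beta.shape[0]}")
    return A @ model.beta + model.alpha


def evaluate(pred, true_ages) -> pd.DataFrame:
    """Per-decade error report: median/mean/std of |error| in years.

    Rows are the seven closed decades 10-19 ... 70-79 plus an 'All' row over
    every subject; decades with no subjects keep count 0 and NaN statistics.
    """
    pred = np.asarray(pred, dtype=float).ravel()
    true_ages = np.asarray(true_ages, dtype=float).ravel()
    if pred.shape != true_ages.shape or pred.size == 0:
        raise ValueError("predictions and ages must be equal-length, non-empty")
    err = np.abs(pred - true_ages)

    def stats(e):
        if e.size == 0:
            return np.nan, np.nan, np.nan
        return (float(np.median(e)), float(np.mean(e)),
                float(np.std(e, ddof=1)) if e.size > 1 else np.nan)

    rows = []
    for lo, hi in DECADES:
        sel = (true_ages >= lo) & (true_ages <= hi)
        med, mean, sd = stats(err[sel])
        rows.append({"age_range": f"{lo}-{hi}", "n": int(sel.sum()),
                     "median_abs_error": med, "mean_abs_error": mean,
                     "std_abs_error": sd})
    med, mean, sd = stats(err)
    rows.append({"age_range": "All", "n": int(err.size),
                 "median_abs_error": med, "mean_abs_error": mean,
                 "std_abs_error": sd})
    return pd.DataFrame(rows)


def save_regression(model: AgeRegressionModel, path) -> None:
    with open(path, "w") as fh:
        json.dump({"beta": model.beta.tolist(), "alpha": model.alpha,
                   "feature_layout": model.feature_layout,
                   "solver": model.solver,
                   "ridge_lambda": model.ridge_lambda}, fh, indent=1)


def load_regression(path) -> AgeRegressionModel:
    with open(path) as fh:
        d = json.load(fh)
    return AgeRegressionModel(beta=np.asarray(d["beta"]), alpha=d["alpha"],
                              feature_layout=d["feature_layout"],
                              solver=d["solver"], ridge_lambda=d["ridge_lambda"])
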