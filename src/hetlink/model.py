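"""Regularized logistic model for edge prediction.

The model predicts treatment probability from: an *unpenalized*
logit-transformed prior (so that degree information enters the model
explicitly instead of confounding the path features), plus standardized
degree and DWPC features under an elastic-net penalty whose strength is
chosen by stratified cross-validation at minimum held-out deviance.

Training is restricted to pairs with a nonzero prior (the prior logit is
infinite otherwise). At prediction time the prior term is replaced by the
logit of a constant prior — typically the overall positive prevalence — so
that every pair is scored on the same degree-agnostic baseline.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.model_selection import StratifiedKFold

from .features import feature_columns
from .hetnet import HetnetError

PRIOR_LOGIT = "prior_logit"


def logit(p: np.ndarray | float, eps: float = 1e-12) -> np.ndarray | float:
    p = np.clip(p, eps, 1.0 - eps)
    return np.log(p / (1.0 - p))


@dataclass
class ModelFit:
    """A fitted elastic-net logistic model with its preprocessing state."""

    feature_names: list[str]
    coefficients: pd.Series  # penalized features, on standardized scale
    intercept: float
    prior_coefficient: float
    means: pd.Series
    stds: pd.Series
    alpha: float
    l1_ratio: float
    cv_results: pd.DataFrame = field(default_factory=pd.DataFrame)

    def standardize(self, X: pd.DataFrame) -> np.ndarray:
        Z = (X[self.feature_names] - self.means) / self.stds
        return Z.to_numpy(dtype=float)

    def linear_predictor(
        self, X: pd.DataFrame, prior_logit: np.ndarray | float
    ) -> np.ndarray:
        Z = self.standardize(X)
        return (
            self.intercept
            + self.prior_coefficient * np.asarray(prior_logit, dtype=float)
            + Z @ self.coefficients.to_numpy()
        )

    def to_dict(self) -> dict:
        return {
            "feature_names": self.feature_names,
            "coefficients": self.coefficients.to_dict(),
            "intercept": self.intercept,
            "prior_coefficient": self.prior_coefficient,
            "means": self.means.to_dict(),
            "stds": self.stds.to_dict(),
            "alpha": self.alpha,
            "l1_ratio": self.l1_ratio,
        }

    @classmethod
    def from_dict(cls, data: dict) -> "ModelFit":
        names = list(data["feature_names"])
        return cls(
            feature_names=names,
            coefficients=pd.Series(data["coefficients"]).reindex(names),
            intercept=float(data["intercept"]),
            prior_coefficient=float(data["prior_coefficient"]),
            means=pd.Series(data["means"]).reindex(names),
            stds=pd.Series(data["stds"]).reindex(names),
            alpha=float(data["alpha"]),
            l1_ratio=float(data["l1_ratio"]),
        )


def _design(
    X: pd.DataFrame,
    names: list[str],
    means: pd.Series,
    stds: pd.Series,
    include_prior: bool,
) -> np.ndarray:
    Z = ((X[names] - means) / stds).to_numpy(dtype=float)
    cols = [np.ones(len(X))]
    if include_prior:
        cols.append(X[PRIOR_LOGIT].to_numpy(dtype=float))
    cols.append(Z)
    return np.column_stack(cols)


def _fit_glmnet(
    design: np.ndarray,
    y: np.ndarray,
    alpha: float,
    l1_ratio: float,
    n_unpenalized: int,
) -> np.ndarray:
    alpha_vec = np.full(design.shape[1], alpha)
    alpha_vec[:n_unpenalized] = 0.0
    model = sm.GLM(y, design, family=sm.families.Binomial())
    result = model.fit_regularized(
        method="elastic_net",
        alpha=alpha_vec,
        L1_wt=l1_ratio,
        maxiter=200,
        cnvrg_tol=1e-7,
    )
    return np.asarray(result.params)


def _deviance(y: np.ndarray, eta: np.ndarray) -> float:
    # mean binomial deviance (2 * negative log-likelihood / n)
    p = 1.0 / (1.0 + np.exp(-eta))
    p = np.clip(p, 1e-12, 1.0 - 1e-12)
    return float(-2.0 * np.mean(y * np.log(p) + (1 - y) * np.log(1 - p)))


def default_alpha_grid(
    design: np.ndarray, y: np.ndarray, l1_ratio: float, n_values: int = 12
) -> np.ndarray:
    """Log-spaced penalty grid from the smallest all-zero penalty downward."""
    penalized = design[:, 2:] if design.shape[1] > 2 else design
    resid = y - y.mean()
    grad = np.abs(penalized.T @ resid) / len(y)
    alpha_max = grad.max() / max(l1_ratio, 1e-3)
    alpha_max = max(alpha_max, 1e-6)
    return np.geomspace(alpha_max, alpha_max * 1e-3, n_values)


def fit_model(
    X: pd.DataFrame,
    y: np.ndarray | pd.Series,
    l1_ratio: float = 0.2,
    alphas: np.ndarray | None = None,
    cv: int = 10,
    seed: int = 0,
    include_prior: bool = True,
) -> ModelFit:
    """Fit the elastic-net logistic model with an unpenalized prior term.

    ``X`` must contain a finite ``prior_logit`` column (training is
    restricted to nonzero-prior pairs) plus transformed feature columns.
    Penalty strength is chosen by ``cv``-fold stratified cross-validation at
    minimum mean held-out deviance, then the model is refit on all rows.
    """
    y = np.asarray(y, dtype=float)
    if len(np.unique(y)) < 2:
        raise HetnetError("fit_model requires both classes")
    names = feature_columns(X)
    if not names:
        raise HetnetError("no feature columns to fit")
    if include_prior:
        if PRIOR_LOGIT not in X.columns:
            raise HetnetError(f"missing {PRIOR_LOGIT!r} column")
        if not np.isfinite(X[PRIOR_LOGIT]).all():
            raise HetnetError(
                "non-finite prior_logit: restrict training to nonzero-prior pairs"
            )
    means = X[names].mean()
    stds = X[names].std(ddof=0).replace(0.0, 1.0)
    design = _design(X, names, means, stds, include_prior)
    n_unpen = 2 if include_prior else 1

    if alphas is None:
        alphas = default_alpha_grid(design, y, l1_ratio)
    alphas = np.asarray(alphas, dtype=float)

    cv_records = []
    if len(alphas) > 1:
        splitter = StratifiedKFold(n_splits=cv, shuffle=True, random_state=seed)
        folds = list(splitter.split(design, y))
        for alpha in alphas:
            deviances = []
            for train_idx, test_idx in folds:
                if len(np.unique(y[train_idx])) < 2:
                    raise HetnetError("single-class training fold")
                params = _fit_glmnet(
                    design[train_idx], y[train_idx], alpha, l1_ratio, n_unpen
                )
                deviances.append(_deviance(y[test_idx], design[test_idx] @ params))
            cv_records.append({"alpha": alpha, "mean_deviance": np.mean(deviances)})
        cv_results = pd.DataFrame(cv_records)
        best_alpha = float(
            cv_results.loc[cv_results["mean_deviance"].idxmin(), "alpha"]
        )
    else:
        cv_results = pd.DataFrame()
        best_alpha = float(alphas[0])

    params = _fit_glmnet(design, y, best_alpha, l1_ratio, n_unpen)
    intercept = float(params[0])
    prior_coef = float(params[1]) if include_prior else 0.0
    coefs = pd.Series(params[n_unpen:], index=names)
    return ModelFit(
        feature_names=names,
        coefficients=coefs,
        intercept=intercept,
        prior_coefficient=prior_coef,
        means=means,
        stds=stds,
        alpha=best_alpha,
        l1_ratio=l1_ratio,
        cv_results=cv_results,
    )


def predict(
    fit: ModelFit,
    X: pd.DataFrame,
    constant_prior: float,
) -> np.ndarray:
    """Treatment probability per pair using a constant prior for every pair.

    ``constant_prior`` is typically the overall positive prevalence, so
    predictions are scaled to it: probability / constant_prior is the
    fold-over-null enrichment.
    """
    if not 0.0 < constant_prior < 1.0:
        raise HetnetError("constant_prior must be in (0, 1)")
    eta = fit.linear_predictor(X, logit(constant_prior))
    return 1.0 / (1.0 + np.exp(-eta))


def prediction_table(
    fit: ModelFit,
    X: pd.DataFrame,
    constant_prior: float,
) -> pd.DataFrame:
    """Predictions with fold-over-null and per-source/target percentile ranks.

    ``X`` must carry ``source`` and ``target`` columns identifying the pair.
    Percentiles report where a prediction ranks among all predictions for
    the same source (resp. target), in percent.
    """
    probs = predict(fit, X, constant_prior)
    table = pd.DataFrame(
        {
            "source": X["source"].to_numpy(),
            "target": X["target"].to_numpy(),
            "probability": probs,
            "fold_over_null": probs / constant_prior,
        }
    )
    table["source_percentile"] = (
        table.groupby("source")["probability"].rank(pct=True) * 100.0
    )
    table["target_percentile"] = (
        table.groupby("target")["probability"].rank(pct=True) * 100.0
    )
    return table.sort_values("probability", ascending=False).reset_index(drop=True)
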