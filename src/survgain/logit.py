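"""Maximum-likelihood logistic regression via iteratively reweighted least
squares, with dummy encoding, mode/median imputation, and explicit detection
of separation and collinearity.

Shared by the propensity model (outcome = treatment arm) and the baseline
response classifier (outcome = response label).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = ["Encoder", "LogitResult", "SeparationError", "CollinearityError", "fit_logit"]

#: |coefficient| beyond which the likelihood is treated as separated.
SEPARATION_BOUND = 15.0


class SeparationError(ValueError):
    """Complete or quasi-complete separation: the MLE does not exist."""


class CollinearityError(ValueError):
    """Linearly dependent design columns; names the columns involved."""


@dataclass
class Encoder:
    """Maps patient covariates to a numeric design matrix.

    Categorical covariates become treatment-coded dummy columns (first level
    is the reference); numeric covariates pass through.  Missing values are
    imputed with the training mode (categorical) / median (numeric), computed
    once at fit time and reused for any later prediction.
    """

    covariates: Sequence[str]
    categorical: Mapping[str, Sequence] = field(default_factory=dict)  # name -> levels
    imputation_values: Mapping[str, object] = field(default_factory=dict)

    @classmethod
    def fit(cls, frame: pd.DataFrame, covariates: Sequence[str]) -> "Encoder":
        categorical, imput = {}, {}
        for name in covariates:
            col = frame[name]
            if col.dtype == object:
                levels = sorted(col.dropna().unique().tolist())
                if not levels:
                    raise ValueError(f"covariate {name!r} is entirely missing")
                categorical[name] = levels
                imput[name] = col.mode(dropna=True).iloc[0]
            else:
                imput[name] = float(col.median(skipna=True))
        return cls(covariates=list(covariates), categorical=categorical,
                   imputation_values=imput)

    @property
    def column_names(self) -> list:
        names = ["intercept"]
        for name in self.covariates:
            if name in self.categorical:
                names += [f"{name}[{lv}]" for lv in self.categorical[name][1:]]
            else:
                names.append(name)
        return names

    def transform(self, frame: pd.DataFrame) -> np.ndarray:
        cols = [np.ones(len(frame))]
        for name in self.covariates:
            col = frame[name]
            if name in self.categorical:
                levels = self.categorical[name]
                filled = col.fillna(self.imputation_values[name])
                unknown = ~filled.isin(levels)
                if unknown.any():
                    bad = filled[unknown].iloc[0]
                    raise ValueError(f"unknown level {bad!r} for covariate {name!r}")
                for lv in levels[1:]:
                    cols.append((filled == lv).to_numpy(dtype=float))
            else:
                cols.append(col.fillna(self.imputation_values[name]).to_numpy(dtype=float))
        return np.column_stack(cols)


@dataclass
class LogitResult:
    coefficients: np.ndarray
    column_names: list
    converged: bool
    n_iterations: int

    def linear_predictor(self, X: np.ndarray) -> np.ndarray:
        return X @ self.coefficients

    def predict(self, X: np.ndarray) -> np.ndarray:
        return 1.0 / (1.0 + np.exp(-self.linear_predictor(X)))


def _check_collinearity(X: np.ndarray, names: Sequence[str]) -> None:
    u, s, vt = np.linalg.svd(X, full_matrices=False)
    if s[0] == 0 or s[-1] / s[0] < 1e-10:
        null = np.abs(vt[-1])
        involved = [names[j] for j in np.flatnonzero(null > 0.1 * null.max())]
        raise CollinearityError(f"collinear design columns: {involved}")


def fit_logit(X: np.ndarray, y: np.ndarray, max_iter: int = 100, tol: float = 1e-8,
              column_names: Sequence[str] | None = None) -> LogitResult:
    """Newton/IRLS fit of Pr(y=1|x) = expit(x'beta).

    Converges when every score (gradient) component is below ``tol`` in
    absolute value.  Any coefficient wandering past ``SEPARATION_BOUND``
    raises :class:`SeparationError` — separation is surfaced, never shrunk
    away.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    names = list(column_names) if column_names is not None else [f"x{j}" for j in range(X.shape[1])]
    _check_collinearity(X, names)

    beta = np.zeros(X.shape[1])
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        p = 1.0 / (1.0 + np.exp(-(X @ beta)))
        score = X.T @ (y - p)
        if np.max(np.abs(score)) < tol:
            converged = True
            break
        w = p * (1.0 - p)
        H = (X * w[:, None]).T @ X
        try:
            step = np.linalg.solve(H, score)
        except np.linalg.LinAlgError as exc:  # flat likelihood ~ separation
            raise SeparationError("singular information matrix during IRLS") from exc
        beta = beta + step
        if np.max(np.abs(beta)) > SEPARATION_BOUND:
            raise SeparationError(
                "coefficient magnitude exceeded "
                f"{SEPARATION_BOUND}; data are (quasi-)separated")
    return LogitResult(coefficients=beta, column_names=names, converged=converged,
                       n_iterations=it)
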