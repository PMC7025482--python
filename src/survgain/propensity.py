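"""Propensity-score estimation and 1-to-k nearest-neighbour matching.

The propensity score PS = Pr(Z=1 | X) is fit by a logit model on the
covariates that significantly affect survival (univariate Cox screening),
then each treated patient is matched to the k controls with the smallest
absolute PS difference, with replacement across treated patients and ties
broken by ascending control id — making the matching deterministic and
order-independent.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .logit import Encoder, LogitResult, fit_logit
from .registry import COVARIATES

__all__ = [
    "PropensityModel",
    "MatchSet",
    "select_covariates",
    "fit_propensity",
    "predict_ps",
    "match_nearest",
]


def _cox_pvalue(durations, events, values, name: str) -> float:
    """Wald p-value from a univariate Cox PH fit (Breslow ties).

    Categorical covariates are dummy-coded and tested jointly
    (chi-square Wald test on all dummy coefficients).
    """
    from lifelines import CoxPHFitter

    df = pd.DataFrame({"T": durations, "E": events})
    if values.dtype == object:
        levels = sorted(pd.Series(values).dropna().unique().tolist())
        for lv in levels[1:]:
            df[f"{name}[{lv}]"] = (values == lv).astype(float)
        k = len(levels) - 1
    else:
        df[name] = values.astype(float)
        k = 1
    cph = CoxPHFitter()
    cph.fit(df, duration_col="T", event_col="E", show_progress=False)
    b = cph.params_.to_numpy()
    V = cph.variance_matrix_.to_numpy()
    chi2 = float(b @ np.linalg.solve(V, b))
    return float(stats.chi2.sf(chi2, df=k))


def _logrank_pvalue(durations, events, values, name: str) -> float:
    """Log-rank alternative: groups = category levels, or a median split for
    continuous covariates."""
    from lifelines.statistics import multivariate_logrank_test

    if values.dtype == object:
        groups = pd.Series(values)
    else:
        v = pd.Series(values.astype(float))
        groups = (v > v.median()).astype(int)
    res = multivariate_logrank_test(durations, groups, events)
    return float(res.p_value)


def select_covariates(cohort: pd.DataFrame, alpha: float = 0.01,
                      candidates: Sequence[str] | None = None,
                      method: str = "cox") -> list:
    """Screen covariates for a significant marginal effect on survival.

    Each candidate is fit in its own univariate survival model against
    observed time (event = death, i.e. not censored); covariates with
    p < ``alpha`` are returned ordered by ascending p-value.  Zero-variance
    or non-converging covariates are skipped with a warning.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if cohort["os_months"].nunique() < 2:
        raise ValueError("cohort needs at least 2 distinct survival times")
    candidates = list(candidates) if candidates is not None else list(COVARIATES)
    test = {"cox": _cox_pvalue, "logrank": _logrank_pvalue}[method]

    results = []
    for name in candidates:
        sub = cohort[["os_months", "censored", name]].dropna(subset=[name])
        values = sub[name].to_numpy()
        if len(pd.unique(values)) < 2:
            warnings.warn(f"covariate {name!r} has zero variance; skipped")
            continue
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                p = test(sub["os_months"].to_numpy(), 1 - sub["censored"].to_numpy(),
                         values, name)
        except Exception as exc:  # non-convergence of one screen
            warnings.warn(f"survival screen failed for {name!r} ({exc}); excluded")
            continue
        if np.isfinite(p) and p < alpha:
            results.append((p, name))
    results.sort()
    return [name for _, name in results]


@dataclass
class PropensityModel:
    """Fitted logit model for Pr(treated=1 | X) with its encoding."""

    selected_covariates: list
    encoder: Encoder
    fit: LogitResult

    @property
    def coefficients(self) -> np.ndarray:
        return self.fit.coefficients

    @property
    def converged(self) -> bool:
        return self.fit.converged

    @property
    def n_iterations(self) -> int:
        return self.fit.n_iterations

    def to_json(self, path) -> None:
        payload = {
            "selected_covariates": list(self.selected_covariates),
            "column_names": self.fit.column_names,
            "coefficients": self.fit.coefficients.tolist(),
            "categorical": {k: list(v) for k, v in self.encoder.categorical.items()},
            "imputation_values": {k: v for k, v in self.encoder.imputation_values.items()},
            "converged": self.fit.converged,
            "n_iterations": self.fit.n_iterations,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, default=float)


def fit_propensity(cohort: pd.DataFrame, covariates: Sequence[str]) -> PropensityModel:
    """ML logistic regression of the treatment indicator on the encoded
    covariates (IRLS; converged when max |score| < 1e-8 or 100 iterations).
    Missing covariate values are imputed by training mode/median."""
    if not covariates:
        raise ValueError("at least one covariate is required")
    if cohort["treated"].nunique() < 2:
        raise ValueError("both arms must be present to fit a propensity model")
    enc = Encoder.fit(cohort, covariates)
    X = enc.transform(cohort)
    y = cohort["treated"].to_numpy(dtype=float)
    fit = fit_logit(X, y, column_names=enc.column_names)
    return PropensityModel(selected_covariates=list(covariates), encoder=enc, fit=fit)


def predict_ps(model: PropensityModel, records: pd.DataFrame) -> pd.Series:
    """Propensity scores for a batch of patients (inverse-logit of the
    linear predictor).  Unknown categorical levels raise."""
    X = model.encoder.transform(records)
    return pd.Series(model.fit.predict(X), index=records["patient_id"].to_numpy(),
                     name="ps")


@dataclass
class MatchSet:
    """1-to-k nearest-neighbour match of treated patients to controls.

    Matching is WITH replacement across treated patients (a control may
    serve several treated patients) but never repeats within one treated
    patient's list; implied weights are w_ij = 1/k.
    """

    k: int
    matches: Mapping[str, list] = field(default_factory=dict)  # treated_id -> [control ids]
    ps_values: Mapping[str, float] = field(default_factory=dict)

    @property
    def n_distinct_controls(self) -> int:
        return len({c for lst in self.matches.values() for c in lst})

    def weights(self, treated_id: str) -> dict:
        return {c: 1.0 / self.k for c in self.matches[treated_id]}

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (t, c, 1.0 / self.k, self.ps_values[t], self.ps_values[c])
            for t, ctrls in self.matches.items()
            for c in ctrls
        ]
        return pd.DataFrame(rows, columns=["treated_id", "control_id", "weight",
                                           "ps_treated", "ps_control"])


def match_nearest(cohort: pd.DataFrame, ps_values: pd.Series, k: int) -> MatchSet:
    """For each treated patient, the k controls minimising |PS_t − PS_c|.

    Ties in PS distance are broken by ascending control patient_id.  Because
    matching is with replacement, the result is independent of treated
    patient order.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    missing = cohort.loc[~cohort["patient_id"].isin(ps_values.index), "patient_id"]
    if len(missing):
        raise ValueError(f"missing propensity score for patient {missing.iloc[0]!r}")
    if ps_values.isna().any():
        raise ValueError("propensity scores contain NaN")

    treated = cohort.loc[cohort["treated"] == 1, "patient_id"].to_numpy()
    controls = np.sort(cohort.loc[cohort["treated"] == 0, "patient_id"].to_numpy())
    if len(controls) < k:
        raise ValueError(f"need at least k={k} controls, have {len(controls)}")

    ps_t = ps_values.loc[treated].to_numpy()
    ps_c = ps_values.loc[controls].to_numpy()
    # distance matrix over id-sorted controls; stable argsort keeps ascending
    # id order within tied distances
    dist = np.abs(ps_t[:, None] - ps_c[None, :])
    order = np.argsort(dist, axis=1, kind="stable")[:, :k]
    matches = {t: controls[order[i]].tolist() for i, t in enumerate(treated)}
    ps_map = {pid: float(ps_values.loc[pid]) for pid in np.concatenate([treated, controls])}
    return MatchSet(k=k, matches=matches, ps_values=ps_map)
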