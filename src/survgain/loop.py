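"""Two-step iterative exploratory learning loop.

Each iteration runs the full pipeline — survival-based covariate screening,
propensity-score fit, 1-to-k matching, survival-gain labeling at threshold
λ, 80/20 split, tree growth with cross-validated pruning, logistic baseline,
ROC evaluation of both — under one configuration.  The loop's two levers are
exactly the configuration's: the covariate set (the analyst's stand-in for
consulting experts about unobserved confounders) and the response definition
(λ).  Iteration stops when the tree AUC stops improving.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import baseline, evaluation, labeling, propensity
from . import tree as cart
from .registry import COVARIATES

__all__ = ["IterationConfig", "IterationReport", "run_iteration", "iterate"]


@dataclass
class IterationConfig:
    """One pass's levers and seeds."""

    lambda_months: float = 1.0
    ps_alpha: float = 0.01
    k: int = 10
    covariate_set: list = field(default_factory=lambda: list(COVARIATES))
    train_fraction: float = 0.8
    seed_split: int = 0
    seed_cv: int = 0
    tree_params: cart.GrowthParams = field(default_factory=cart.GrowthParams)
    cv_rule: str = "min"
    notes: str = ""


@dataclass
class IterationReport:
    config: IterationConfig
    selected_covariates: list
    n_matched_controls: int
    trr: float
    tree_summary: str
    tree_split_variables: list
    selected_cp: Optional[float]
    tree_auc: float
    tree_sensitivity: float
    tree_specificity: float
    logistic_auc: float
    logistic_sensitivity: float
    logistic_specificity: float
    delta_auc: Optional[float] = None      # vs previous iteration's tree AUC
    truth_agreement: Optional[float] = None  # label vs true responder status
    is_best: bool = False

    def summary_row(self) -> dict:
        return {
            "lambda_months": self.config.lambda_months,
            "trr": self.trr,
            "tree_auc": self.tree_auc,
            "logistic_auc": self.logistic_auc,
            "delta_auc": self.delta_auc,
        }


class StageError(RuntimeError):
    """Pipeline failure annotated with the stage that raised it."""


def _stage(name, fn, *args, **kwargs):
    try:
        return fn(*args, **kwargs)
    except Exception as exc:
        raise StageError(f"stage {name!r} failed: {exc}") from exc


def run_iteration(cohort: pd.DataFrame, config: IterationConfig,
                  truth: Optional[pd.Series] = None) -> IterationReport:
    """Execute the full pipeline once, deterministically given the config's
    seeds.  When the cohort carries ground-truth ITEs, the fraction of
    treated patients whose label agrees with their true responder status
    (true ITE > λ) is reported as well."""
    selected = _stage("select_covariates", propensity.select_covariates,
                      cohort, alpha=config.ps_alpha, candidates=config.covariate_set)
    if not selected:  # fall back to the configured set rather than aborting
        selected = list(config.covariate_set)
    ps_model = _stage("fit_propensity", propensity.fit_propensity, cohort, selected)
    ps = _stage("predict_ps", propensity.predict_ps, ps_model, cohort)
    matches = _stage("match_nearest", propensity.match_nearest, cohort, ps, config.k)
    sg = _stage("survival_gain", labeling.survival_gain, matches, cohort)
    labeled = _stage("label_response", labeling.label_response, sg,
                     config.lambda_months, cohort=cohort, matchset=matches)

    treated = cohort[cohort["treated"] == 1].set_index("patient_id")
    data = treated.loc[labeled.response.index, config.covariate_set].reset_index()
    data["response"] = labeled.response.to_numpy()
    train, test = _stage("split_train_test", evaluation.split_train_test,
                         data, config.train_fraction, config.seed_split)

    grown = _stage("grow_tree", cart.grow_tree, train[config.covariate_set],
                   train["response"], config.tree_params)
    pruned = _stage("prune_cv", cart.prune_cv, grown, train[config.covariate_set],
                    train["response"], 10, config.seed_cv, config.cv_rule)
    tree_scores = _stage("predict_proba", cart.predict_proba, pruned, test)

    logit = _stage("fit_logistic", baseline.fit_logistic, train, train["response"],
                   config.covariate_set)
    logit_scores = _stage("predict_response_prob", baseline.predict_response_prob,
                          logit, test)

    y_test = test["response"].to_numpy()

    def _score(scores):
        if len(np.unique(scores)) < 2 or len(np.unique(y_test)) < 2:
            # degenerate: constant scores or single-class test labels
            return 0.5, float("nan"), float("nan")
        roc = evaluation.roc_curve(y_test, scores)
        _, sens, spec = roc.operating_point
        return roc.auc, sens, spec

    tree_auc, tree_sens, tree_spec = _score(tree_scores)
    log_auc, log_sens, log_spec = _score(logit_scores)

    agreement = None
    if truth is not None:
        true_resp = (truth.reindex(labeled.response.index) > config.lambda_months)
        agreement = float((labeled.response == true_resp.astype(int)).mean())

    return IterationReport(
        config=config,
        selected_covariates=selected,
        n_matched_controls=matches.n_distinct_controls,
        trr=labeled.trr,
        tree_summary=cart.render_text(pruned),
        tree_split_variables=pruned.split_variables(),
        selected_cp=pruned.selected_cp,
        tree_auc=tree_auc, tree_sensitivity=tree_sens, tree_specificity=tree_spec,
        logistic_auc=log_auc, logistic_sensitivity=log_sens,
        logistic_specificity=log_spec,
        truth_agreement=agreement,
    )


def iterate(cohort: pd.DataFrame, configs: Sequence[IterationConfig],
            tol: float = 0.005, patience: int = 1,
            truth: Optional[pd.Series] = None) -> list:
    """Run configurations in order, stopping early once the tree AUC has
    failed to improve by ``tol`` for ``patience`` consecutive iterations.
    The argmax-AUC report is flagged ``is_best``."""
    if not configs:
        raise ValueError("need at least one configuration")
    reports: list = []
    stall = 0
    for config in configs:
        report = run_iteration(cohort, config, truth=truth)
        if reports:
            report.delta_auc = report.tree_auc - reports[-1].tree_auc
        reports.append(report)
        if report.delta_auc is not None and report.delta_auc < tol:
            stall += 1
            if stall >= patience:
                break
        else:
            stall = 0
    best = int(np.argmax([r.tree_auc for r in reports]))
    reports[best].is_best = True
    return reports
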