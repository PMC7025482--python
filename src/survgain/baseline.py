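"""Logistic-regression baseline classifier for the response label.

The comparison model for the classification tree: a plain multivariable
logistic regression of the binary response on the patient covariate schema,
with mode/median imputation for missing values (a logit model cannot use
surrogate splits).  No regularization — separation is surfaced as an error.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .logit import Encoder, LogitResult, fit_logit
from .registry import COVARIATES

__all__ = ["LogisticClassifier", "fit_logistic", "predict_response_prob"]


@dataclass
class LogisticClassifier:
    covariates: list
    encoder: Encoder
    fit: LogitResult

    @property
    def coefficients(self) -> np.ndarray:
        return self.fit.coefficients

    @property
    def converged(self) -> bool:
        return self.fit.converged

    def to_json(self, path) -> None:
        payload = {
            "covariates": list(self.covariates),
            "column_names": self.fit.column_names,
            "coefficients": self.fit.coefficients.tolist(),
            "categorical": {k: list(v) for k, v in self.encoder.categorical.items()},
            "imputation_values": dict(self.encoder.imputation_values),
            "converged": self.fit.converged,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, default=float)


def fit_logistic(frame: pd.DataFrame, response, covariates: Sequence[str] | None = None
                 ) -> LogisticClassifier:
    """ML logistic fit of Pr(response=1 | covariates) by IRLS.

    Defaults to the full patient covariate schema.  Imputation values are
    computed on the training rows and reused at prediction time.
    """
    covariates = list(covariates) if covariates is not None else list(COVARIATES)
    enc = Encoder.fit(frame, covariates)
    X = enc.transform(frame)
    y = np.asarray(response, dtype=float)
    fit = fit_logit(X, y, column_names=enc.column_names)
    return LogisticClassifier(covariates=covariates, encoder=enc, fit=fit)


def predict_response_prob(model: LogisticClassifier, records: pd.DataFrame) -> np.ndarray:
    """Inverse-logit of the linear predictor for each record."""
    return model.fit.predict(model.encoder.transform(records))
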