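"""Survival-gain computation and binary response labeling.

For a treated patient i matched to controls C(i) with weights w_ij = 1/k,
the survival gain is

    SG_i = OS_i - sum_{j in C(i)} w_ij * OS_j

i.e. the observed treated survival minus the equal-weighted mean survival of
the matched controls.  A treated patient is labeled a responder when SG
exceeds a threshold λ (strictly: SG > λ).  Observed times are used as-is,
treating survival as uncensored — censoring is rare in the target setting,
and patients censored with SG ≤ λ are counted as potentially mislabeled
rather than dropped (an optional strict mode drops them).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from .propensity import MatchSet

__all__ = ["LabeledCohort", "survival_gain", "label_response", "response_rate_curve"]


@dataclass
class LabeledCohort:
    """Treated patients annotated with survival gain and response label."""

    lambda_months: float
    sg: pd.Series          # treated patient_id -> months
    response: pd.Series    # treated patient_id -> 0/1
    trr: float             # treatment response rate = mean(response)
    censoring_note: Mapping[str, int] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"patient_id": self.sg.index, "sg_months": self.sg.to_numpy(),
                             "response": self.response.to_numpy()})

    def summary(self) -> dict:
        return {"lambda_months": self.lambda_months, "trr": self.trr,
                "n_treated": int(len(self.response)),
                "n_responders": int(self.response.sum()),
                **{k: int(v) for k, v in self.censoring_note.items()}}


def survival_gain(matchset: MatchSet, cohort: pd.DataFrame) -> pd.Series:
    """SG per treated patient, in months."""
    os_months = cohort.set_index("patient_id")["os_months"]
    out = {}
    for tid, ctrls in matchset.matches.items():
        try:
            os_t = os_months.loc[tid]
            os_c = os_months.loc[ctrls]
        except KeyError as exc:
            raise ValueError(f"patient {exc.args[0]!r} missing from cohort") from exc
        out[tid] = float(os_t - os_c.mean())
    return pd.Series(out, name="sg_months")


def label_response(sg: pd.Series, lambda_months: float,
                   cohort: pd.DataFrame | None = None,
                   matchset: MatchSet | None = None,
                   strict: bool = False) -> LabeledCohort:
    """Binarize survival gain at threshold λ (responder iff SG > λ, strictly).

    When the cohort is supplied, counts censored treated patients whose
    SG ≤ λ — the group that may be wrongly labeled non-responders because
    their survival was cut short by follow-up, not death — and censored
    matched controls.  ``strict=True`` drops those ambiguous treated
    patients from the labeled cohort instead of keeping the default label.
    """
    if lambda_months <= 0:
        raise ValueError("lambda_months must be > 0")
    response = (sg > lambda_months).astype(int)

    note = {}
    if cohort is not None:
        cens = cohort.set_index("patient_id")["censored"]
        cens_treated = cens.reindex(sg.index).fillna(0).astype(bool)
        ambiguous = cens_treated & (sg <= lambda_months)
        note["censored_treated"] = int(cens_treated.sum())
        note["censored_treated_possibly_mislabeled"] = int(ambiguous.sum())
        if matchset is not None:
            matched_controls = {c for lst in matchset.matches.values() for c in lst}
            note["censored_matched_controls"] = int(cens.loc[sorted(matched_controls)].sum())
        if strict:
            keep = ~ambiguous
            sg, response = sg[keep], response[keep]
    trr = float(response.mean()) if len(response) else float("nan")
    return LabeledCohort(lambda_months=float(lambda_months), sg=sg, response=response,
                         trr=trr, censoring_note=note)


def response_rate_curve(sg: pd.Series, lambdas: Sequence[float]) -> list:
    """TRR as a function of λ; non-increasing in λ."""
    if len(lambdas) == 0:
        raise ValueError("need at least one lambda")
    if any(lam <= 0 for lam in lambdas):
        raise ValueError("all lambdas must be > 0")
    return [(float(lam), float((sg > lam).mean())) for lam in lambdas]
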