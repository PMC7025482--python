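import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import survgain as sg

settings.register_profile(
    "default", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow], deadline=None)
settings.load_profile("default")


def run_pipeline(seed: int, n: int = 3000, null: bool = False, k: int = 10,
                 with_tree: bool = True) -> dict:
    """Full pipeline on one synthetic cohort; returns the per-seed summary
    used by recovery/calibration checks."""
    overrides = {"ite_rule": ()} if null else {}
    cfg = sg.default_config(n_patients=n, seed=seed, **overrides)
    coh = sg.generate_cohort(cfg)
    frame = coh.frame
    selected = sg.select_covariates(frame, alpha=0.01)
    model = sg.fit_propensity(frame, selected)
    ps = sg.predict_ps(model, frame)
    matches = sg.match_nearest(frame, ps, k=k)
    gain = sg.survival_gain(matches, frame)
    labeled = sg.label_response(gain, 1.0)
    truth_treated = coh.truth.loc[gain.index]
    out = {
        "seed": seed,
        "trr1": labeled.trr,
        "trr3": sg.label_response(gain, 3.0).trr,
        "sg_bias": float(gain.mean() - truth_treated.mean()),
        "n_matched_controls": matches.n_distinct_controls,
    }
    if not with_tree:
        return out

    treated = frame[frame["treated"] == 1].set_index("patient_id")
    data = treated.loc[labeled.response.index, sg.COVARIATES].reset_index()
    data["response"] = labeled.response.to_numpy()
    train, test = sg.split_train_test(data, 0.8, seed=seed + 1000)
    grown = sg.grow_tree(train[sg.COVARIATES], train["response"])
    pruned = sg.prune_cv(grown, train[sg.COVARIATES], train["response"],
                         n_folds=10, seed=seed + 2000)
    scores = sg.predict_proba(pruned, test)
    if len(np.unique(scores)) < 2 or test["response"].nunique() < 2:
        auc = 0.5  # constant scores: ROC collapses to the diagonal
    else:
        auc = sg.roc_curve(test["response"], scores).auc
    out.update({
        "auc": auc,
        "split_variables": pruned.split_variables(),
        "n_splits": len(pruned.split_variables()),
    })
    return out


@pytest.fixture(scope="session")
def planted_runs():
    """Full-pipeline runs on 20 planted-effect cohorts (n=3000, k=10, λ=1)."""
    return [run_pipeline(seed, n=3000) for seed in range(1, 21)]


@pytest.fixture
def small_cohort():
    """A small deterministic synthetic cohort for cheap integration tests."""
    return sg.generate_cohort(sg.default_config(n_patients=600, seed=7))


def make_random_cohort_frame(rng: np.random.Generator, n: int) -> pd.DataFrame:
    """Minimal valid cohort frame with random PS-irrelevant content; used by
    matching oracle tests."""
    treated = rng.integers(0, 2, size=n)
    if treated.sum() == 0:
        treated[0] = 1
    if treated.sum() == n:
        treated[0] = 0
    return pd.DataFrame({
        "patient_id": [f"P{i:04d}" for i in range(n)],
        "treated": treated,
        "os_months": rng.uniform(0, 40, size=n),
        "censored": np.zeros(n, dtype=int),
        "age": rng.integers(20, 90, size=n).astype(float),
        "sex": rng.integers(0, 2, size=n).astype(float),
        "who_score": rng.integers(0, 5, size=n).astype(float),
        "rpa_class": rng.choice(["III", "IV", "V"], size=n),
        "surgery": rng.integers(0, 2, size=n).astype(float),
        "radiotherapy": rng.integers(0, 2, size=n).astype(float),
        "chemotherapy": rng.integers(0, 2, size=n).astype(float),
    })
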