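"""Label treated patients as responders via matched survival gain.

Runs the initialization half of the pipeline: screen covariates against
survival, fit the propensity score, match each treated patient to its 10
nearest controls, compute the survival gain SG_i = OS_i - mean(matched
control OS), and binarize at λ = 1 month.
"""

import survgain as sg

cohort = sg.generate_cohort(sg.default_config(n_patients=4500, seed=1))
frame = cohort.frame

selected = sg.select_covariates(frame, alpha=0.01)
print("covariates with a significant survival effect (p < 0.01):", selected)

model = sg.fit_propensity(frame, selected)
ps = sg.predict_ps(model, frame)
matches = sg.match_nearest(frame, ps, k=10)
print(f"{matches.n_distinct_controls} distinct controls matched to "
      f"{len(matches.matches)} treated patients (with replacement)")

gain = sg.survival_gain(matches, frame)
labeled = sg.label_response(gain, 1.0, cohort=frame, matchset=matches)
print(f"\nsurvival gain: mean {gain.mean():+.2f} months, sd {gain.std():.2f}")
print(f"TRR(λ=1) = {labeled.trr:.1%}  "
      f"({int(labeled.response.sum())} of {len(labeled.response)} responders)")
print(f"censored treated possibly mislabeled non-responders: "
      f"{labeled.censoring_note['censored_treated_possibly_mislabeled']}")

print("\nTRR as the response threshold λ rises (non-increasing):")
for lam, trr in sg.response_rate_curve(gain, [0.5, 1, 2, 3, 6]):
    print(f"  λ={lam:>3.1f} months  TRR={trr:.1%}")

truth = cohort.truth.loc[gain.index]
print(f"\nground truth check: mean SG {gain.mean():+.2f} vs "
      f"mean planted effect among treated {truth.mean():+.2f} months — "
      "matching recovers the average effect despite confounding.")
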