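"""Select prognostic markers by componentwise likelihood boosting.

Draws a training-sized cohort (728 samples, 150 candidate segments, six
prognostic), runs 100 boosting steps of the penalized Cox update, and
compares the selected set against the planted truth.
"""

from cnisig.cox_models import BoostConfig, coxboost_select
from cnisig.simulate import simulate_marker_cohort

doses, outcome, true_beta = simulate_marker_cohort(n_samples=728, seed=3)
result = coxboost_select(doses, outcome[["time_months", "event"]],
                         config=BoostConfig(steps=100))

true = set(true_beta.index[true_beta != 0])
selected = set(result.selected)
print(f"events in cohort: {outcome['event'].sum()}")
print(f"selected {len(selected)} of 150 candidate segments")
print(f"  true positives: {sorted(selected & true)}")
print(f"  false positives: {sorted(selected - true)}")
print(f"  missed: {sorted(true - selected)}")
print("\nboosted coefficients of the selected markers:")
print(result.coefs[result.selected].round(3).to_string())
# Boosted coefficients are shrunken toward zero relative to the planted
# values — the penalty trades bias for sparse, stable selection.
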