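"""Classify samples into low / no-CNI / high risk groups.

The risk index is the inner product of each sample's dose vector with the
training coefficients; its sign splits imbalance carriers into high and low
risk, while samples with no imbalance at any selected marker form the
intermediate no-CNI group.
"""

import numpy as np

from cnisig.cox_models import BoostConfig, coxboost_select
from cnisig.discrimination import log_rank
from cnisig.risk import classify_risk, group_hazards, group_summary
from cnisig.simulate import simulate_marker_cohort

doses, outcome, _ = simulate_marker_cohort(n_samples=728, seed=4)
boost = coxboost_select(doses, outcome[["time_months", "event"]],
                        config=BoostConfig(steps=100))

classification = classify_risk(doses[boost.selected],
                               boost.coefs[boost.selected])
print(group_summary(classification).round(3).to_string())

labels = classification["group"].to_numpy()
hr = group_hazards(labels, outcome[["time_months", "event"]])
print("\nhazard ratios vs the no-CNI reference:")
print(hr.round(3).to_string())
lr = log_rank(outcome[["time_months", "event"]], labels)
print(f"\nlog-rank across groups: chi2={lr.chi2:.1f}, p={lr.p:.2e}")
# A high-risk HR above 1 and low-risk HR below 1 with a small log-rank p
# show the index separates recurrence risk in the direction it was built to.
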