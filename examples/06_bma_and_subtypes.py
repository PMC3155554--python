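"""Model-averaged evidence per marker and subtype-specific frequencies.

BMA weighs every Cox model on the selected markers by exp(-BIC/2) and sums
posteriors over models containing each marker; the frequency test asks which
segments differ in gain/loss frequency across tumour subtypes, with a
permutation-based FDR.
"""

import numpy as np

from cnisig.bma import bma_posterior_effects
from cnisig.simulate import simulate_marker_cohort
from cnisig.subtypes import subtype_frequency_test

doses, outcome, beta = simulate_marker_cohort(
    n_samples=800, n_segments=10, prognostic_betas=(1.0, -0.8, 0.6),
    carrier_freq=0.4, seed=6)
res = bma_posterior_effects(doses.astype(float),
                            outcome[["time_months", "event"]])
print(f"{outcome['event'].sum()} events; true effects are seg0000-seg0002")
print("posterior effect probabilities:")
for name, p in res.effect_probability.items():
    print(f"  {name}: {p:5.1%}  ({res.categories[name]})")

rng = np.random.default_rng(6)
labels = rng.choice(["LUM A", "LUM B", "HER2", "TNBC"], len(doses))
freq = np.where(labels == "TNBC", 0.45, 0.08)
doses["tnbc_gain"] = (rng.random(len(doses)) < freq).astype(int)
ft = subtype_frequency_test(doses, labels, b_perm=500, seed=6)
row = ft.set_index("segment_id").loc["tnbc_gain"]
print(f"\nplanted TNBC-enriched gain: p = {row['p']:.2e}, "
      f"permutation FDR = {row['fdr']:.3f}")
# Markers with posterior probability above 95% carry strong evidence of a
# real effect; the planted subtype-specific event should clear FDR < 0.01.
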