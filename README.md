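# cnisig

Copy-number imbalance (CNI) prognostic signatures for early-stage breast
cancer — a tested Python implementation of the full analysis chain from
probe-level copy-number profiles to validated risk groups.

Archival FFPE tumour collections with long follow-up can be profiled for
copy number with molecular-inversion-probe (MIP) arrays.  This package
implements the statistical pipeline that turns such profiles into a
recurrence-risk signature, and pairs it with a synthetic-cohort generator so
every stage can be verified against planted ground truth:

1. **Reduction & segmentation** — running medians over groups of 25
   consecutive probes, then per-sample circular binary segmentation (CBS):
   the arc of bins maximising the two-sample t statistic is tested against a
   within-span permutation null at α = 0.01 and accepted splits are recursed.
2. **Dose coding** — segment means are called against linear-scale
   thresholds (≥2.5 one copy gained, ≤1.5 one copy lost), giving each sample
   a dose x_ij ∈ {−1, 0, +1} per segment; adjacent segments whose calls
   agree in ≥99.5% of samples are recombined into a common genome-wide grid.
3. **Marker selection** — componentwise likelihood boosting for the Cox
   model: each of M = 100 steps updates the single segment with the best
   penalized score gain U²/(I + λ), λ defaulting to 9 × the number of
   events.  Segments with nonzero boosted coefficients form the signature.
4. **Risk grouping** — the risk index r_i = Σ_j β_j x_ij splits carriers
   into high (r > 0) and low (r < 0) risk, with imbalance-free samples as
   the intermediate no-CNI group.
5. **Evaluation** — Harrell's C-index with bootstrap model comparison,
   Kaplan–Meier-weighted time-dependent ROC at 5/10 years, KM/log-rank, AIC
   backwards elimination for the clinical covariates, and BIC-based Bayesian
   model averaging for per-marker posterior effect probabilities.
6. **Subtype analyses** — IHC-style subtype rules (HER2 by ERBB2 copy
   number > 2.8; ER+ tumours split at Ki67 20% into luminal A/B; ER−/PR− as
   triple-negative), recurrent-CNI detection at ≥10% frequency, and
   per-segment subtype association tests with a permutation plug-in FDR.

## Worked example

```python
from cnisig.cox_models import BoostConfig, coxboost_select
from cnisig.simulate import simulate_marker_cohort

doses, outcome, true_beta = simulate_marker_cohort(n_samples=728, seed=3)
result = coxboost_select(doses, outcome[["time_months", "event"]],
                         config=BoostConfig(steps=100))
print(sorted(result.selected))
```

prints

```
['seg0000', 'seg0001', 'seg0002', 'seg0003', 'seg0004']
```

— five of the six segments planted with nonzero log-hazard (the sixth,
weakest effect is missed at this seed) and no false positives out of 150
candidates.  `examples/` contains one short narrative script per capability
(simulation, segmentation, selection, risk groups, model evaluation,
BMA/subtype frequencies); each prints the numbers it computes with a line on
how to read them.  A thin CLI mirrors the pipeline stages:

```bash
cnisig run-all --n-samples 400 --seed 1 --out my_run
```

writes the full report bundle (SEG segments, segment grid, dose matrix,
selected markers, model metrics, risk groups, BMA table, manifest) as
plain-text files.

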