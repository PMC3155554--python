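"""Run the full pipeline and compare the four model families.

Simulates, segments, selects markers, classifies risk, and scores the
clinical, clinical+subtype, markers-only and full Cox models by test-set
concordance and time-dependent AUC at 5 and 10 years.
"""

from cnisig.pipeline import PipelineConfig, run_full_analysis
from cnisig.simulate import default_config

config = PipelineConfig(out_dir="scratch/example_run",
                        simulation=default_config(n_samples=300, seed=5),
                        split_seed=5)
res = run_full_analysis(config)

cols = ["model", "c_index_train", "c_index_test", "auc_60m_test",
        "auc_120m_test"]
print(res["metrics"][cols].round(3).to_string(index=False))
print(f"\nselected markers: {res['selected']}")
print(f"full vs clinical test-set comparison: p = {res['comparison'].p:.2e}")
# The full model (markers + clinical + subtype) should post the highest
# test-set C-index; the gap over the clinical model is the value the
# copy-number signature adds to standard prognostic factors.
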