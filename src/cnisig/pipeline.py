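"""End-to-end orchestration: simulate → segment → select → classify → evaluate.

`run_full_analysis` drives the whole chain on a synthetic cohort and writes a
report bundle of plain-text artifacts: per-sample SEG segments, the common
grid and dose matrix, the selected markers with their training-set Cox table,
a model-discrimination table for the four model families (clinical;
clinical + subtype; markers; full), the risk-group classification with
Kaplan–Meier/log-rank summaries, the BMA posterior-effect table, and a run
manifest recording every seed and parameter.  Identical configurations
produce identical bundles.
"""

from __future__ import annotations

import logging
import time as _time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io
from .bma import BmaConfig, bma_posterior_effects
from .cox_models import BoostConfig, backwards_eliminate_aic, cox_fit, \
    coxboost_select, split_cohort
from .discrimination import compare_cindex, concordance_index, km_curve, \
    log_rank, td_roc
from .risk import classify_risk, group_hazards, group_summary
from .segmentation import SegmentationParams, build_common_grid, \
    reduce_running_median, segment_profiles
from .simulate import SimulationConfig, default_config, default_layout, \
    simulate_cohort
from .subtypes import assign_subtypes

__all__ = ["PipelineConfig", "run_full_analysis", "model_design_matrices"]

log = logging.getLogger("cnisig")

CLINICAL_COVARIATES = ["age_le50", "size_ge2cm", "node_positive"]
SUBTYPE_DUMMIES = ["LUM B", "HER2", "TNBC"]  # LUM A is the reference


@dataclass
class PipelineConfig:
    out_dir: str = "cnisig_run"
    simulation: SimulationConfig = field(default_factory=default_config)
    segmentation: SegmentationParams = field(default_factory=SegmentationParams)
    boost: BoostConfig = field(default_factory=BoostConfig)
    bma: BmaConfig = field(default_factory=BmaConfig)
    train_fraction: float = 0.75
    split_seed: int = 0
    roc_horizons: tuple = (60.0, 120.0)  # months
    compare_bootstrap: int = 200


def model_design_matrices(clinical: pd.DataFrame, subtypes: pd.Series,
                          doses_selected: pd.DataFrame):
    """Design matrices for the four model families, indexed by sample.

    Subtype enters as indicator columns against the LUM A reference;
    unclassified samples carry zeros on all three indicators.
    """
    clin = clinical.set_index("sample")[CLINICAL_COVARIATES].astype(float)
    sub = pd.DataFrame({d: (subtypes == d).astype(float) for d in SUBTYPE_DUMMIES},
                       index=subtypes.index)
    designs = {
        "clinical": clin,
        "clinical+subtype": clin.join(sub),
        "markers": doses_selected.astype(float),
        "full": clin.join(sub).join(doses_selected.astype(float)),
    }
    return designs


def _evaluate_models(designs, outcome_by_sample, train, test, horizons,
                     forced=("age_le50",), b_boot=200):
    """Fit each family on the training set and score both splits.

    The full model goes through AIC backwards elimination (age forced); the
    others are plain multivariate fits.  Returns (metrics table, fits,
    test-set log-hazard scores).
    """
    rows = []
    fits = {}
    scores = {}
    out_train = outcome_by_sample.loc[train].reset_index(drop=True)
    out_test = outcome_by_sample.loc[test].reset_index(drop=True)
    for name, X in designs.items():
        Xt = X.loc[train].reset_index(drop=True)
        if name == "full":
            fit = backwards_eliminate_aic(
                Xt, out_train, forced=tuple(f for f in forced if f in X.columns))
        else:
            fit = cox_fit(Xt, out_train)
        fits[name] = fit
        row = {"model": name, "n_covariates": int((fit.coefs != 0).sum())}
        for split, ids, out in (("train", train, out_train),
                                ("test", test, out_test)):
            lh = fit.predict_log_hazard(X.loc[ids].reset_index(drop=True))
            cr = concordance_index(lh, out)
            row[f"c_index_{split}"] = cr.c
            row[f"c_index_se_{split}"] = cr.se
            for h in horizons:
                try:
                    row[f"auc_{int(h)}m_{split}"] = td_roc(lh, out, h).auc
                except ValueError:
                    row[f"auc_{int(h)}m_{split}"] = np.nan
            if split == "test":
                scores[name] = lh.to_numpy()
        rows.append(row)
    metrics = pd.DataFrame(rows)
    comp = compare_cindex(scores["full"], scores["clinical"], out_test,
                          b_boot=b_boot, seed=0)
    return metrics, fits, scores, comp


def run_full_analysis(config: PipelineConfig) -> dict:
    """Run the whole pipeline; returns a dict of in-memory results.

    Artifacts are written under ``config.out_dir``; any stage failure is
    re-raised with the stage name, leaving a FAILED marker alongside the
    partial outputs.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"parameters": {
        "simulation_seed": config.simulation.seed,
        "split_seed": config.split_seed,
        "train_fraction": config.train_fraction,
        "boost_steps": config.boost.steps,
        "segmentation_alpha": config.segmentation.alpha,
        "group_size": config.segmentation.group_size,
        "agreement": config.segmentation.agreement,
        "n_samples": config.simulation.n_samples,
    }}
    stage = "setup"
    try:
        stage = "simulate"
        t0 = _time.perf_counter()
        pm, truth, clinical, survival = simulate_cohort(config.simulation,
                                                        default_layout())
        io.write_probe_matrix(pm, out / "probe_matrix.tsv")
        io.write_clinical(clinical, out / "clinical.csv")
        io.write_survival(survival, out / "survival.csv")
        log.info("stage %s: %.1fs", stage, _time.perf_counter() - t0)

        stage = "segment"
        t0 = _time.perf_counter()
        reduced = reduce_running_median(pm, config.segmentation.group_size,
                                        config.segmentation.keep_remainder_bin)
        profiles = segment_profiles(reduced, config.segmentation,
                                    seed=config.simulation.seed)
        grid, doses = build_common_grid(profiles, reduced, config.segmentation)
        io.write_seg(profiles, out / "segments.seg")
        io.write_grid(grid, out / "segment_grid.tsv")
        io.write_dose_matrix(doses, out / "dose_matrix.tsv")
        log.info("stage %s: %.1fs", stage, _time.perf_counter() - t0)

        stage = "split"
        train, test = split_cohort(list(doses.index), config.train_fraction,
                                   config.split_seed)

        stage = "select"
        t0 = _time.perf_counter()
        outcome = survival.set_index("sample")[["time_months", "event"]]
        boost = coxboost_select(doses.loc[train],
                                outcome.loc[train].reset_index(drop=True),
                                config=config.boost)
        selected = boost.selected
        sel_table = pd.DataFrame({
            "segment_id": selected,
            "boosted_coef": boost.coefs[selected].to_numpy(),
            "hr_per_dose": np.exp(boost.coefs[selected].to_numpy()),
        })
        sel_table.to_csv(out / "selected_markers.tsv", sep="\t", index=False)
        log.info("stage %s: %.1fs", stage, _time.perf_counter() - t0)
        manifest["n_selected"] = len(selected)

        stage = "classify"
        subtypes = assign_subtypes(clinical)
        doses_sel = doses[selected] if selected else doses.iloc[:, :0]
        if selected:
            classification = classify_risk(doses_sel, boost.coefs[selected])
        else:
            classification = pd.DataFrame({
                "risk_index": 0.0, "n_markers_nonzero": 0, "group": "no-CNI",
            }, index=doses.index)
        classification.rename_axis("sample").to_csv(out / "risk_groups.csv")
        group_summary(classification).rename_axis("group").to_csv(
            out / "risk_group_summary.csv")
        labels = classification["group"].to_numpy()
        groups_present = pd.unique(labels)
        if len(groups_present) > 1 and "no-CNI" in groups_present:
            ghr = group_hazards(labels, outcome.loc[classification.index]
                                .reset_index(drop=True))
            ghr.rename_axis("contrast").to_csv(out / "group_hazards.csv")
            lr = log_rank(outcome.loc[classification.index].reset_index(drop=True),
                          labels)
            curves = km_curve(outcome.loc[classification.index]
                              .reset_index(drop=True), labels)
        else:
            ghr, lr, curves = None, None, None

        stage = "evaluate"
        t0 = _time.perf_counter()
        designs = model_design_matrices(clinical, subtypes, doses_sel)
        metrics, fits, scores, comp = _evaluate_models(
            designs, outcome, train, test, config.roc_horizons,
            b_boot=config.compare_bootstrap)
        metrics.to_csv(out / "model_metrics.tsv", sep="\t", index=False,
                       float_format="%.4f")
        fits["full"].summary.rename_axis("factor").to_csv(
            out / "full_model.tsv", sep="\t", float_format="%.4g")
        log.info("stage %s: %.1fs", stage, _time.perf_counter() - t0)

        stage = "bma"
        t0 = _time.perf_counter()
        if selected:
            bma_res = bma_posterior_effects(
                doses_sel.loc[train].astype(float).reset_index(drop=True),
                outcome.loc[train].reset_index(drop=True), config.bma)
            bma_table = pd.DataFrame({
                "posterior_effect_probability": bma_res.effect_probability,
                "category": bma_res.categories,
            })
            bma_table.rename_axis("segment_id").to_csv(
                out / "bma_effects.tsv", sep="\t", float_format="%.4f")
        else:
            bma_res = None
        log.info("stage %s: %.1fs", stage, _time.perf_counter() - t0)

        stage = "report"
        subtype_counts = subtypes.value_counts()
        report = {
            "n_samples": int(len(doses)),
            "n_train": len(train), "n_test": len(test),
            "n_common_segments": int(len(grid)),
            "n_selected_markers": len(selected),
            "subtype_counts": {k: int(v) for k, v in subtype_counts.items()},
            "risk_group_fractions": {
                k: float(v) for k, v in
                group_summary(classification)["fraction"].items()},
            "full_vs_clinical_test_p": comp.p,
            "log_rank_p_risk_groups": None if lr is None else lr.p,
        }
        io.write_json(report, out / "report.json")
        io.write_json(manifest, out / "manifest.json")
    except Exception as exc:
        (out / "FAILED").write_text(f"stage={stage}: {exc}\n")
        raise RuntimeError(f"pipeline failed at stage '{stage}': {exc}") from exc

    return {
        "probe_matrix": pm, "truth": truth, "clinical": clinical,
        "survival": survival, "reduced": reduced, "profiles": profiles,
        "grid": grid, "doses": doses, "train": train, "test": test,
        "boost": boost, "selected": selected, "classification": classification,
        "group_hazards": ghr, "log_rank": lr, "km_curves": curves,
        "metrics": metrics, "fits": fits, "comparison": comp, "bma": bma_res,
        "report": report,
    }
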