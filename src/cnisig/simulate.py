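"""Synthetic cohorts with planted copy-number imbalances and Cox-linked outcomes.

The generator emulates the statistical structure of a MIP-array breast-cancer
cohort: a near-diploid probe-level copy-number matrix (linear scale, baseline
2.0) with contiguous planted gain/loss events whose frequencies depend on
tumour subtype, immunohistochemistry-style marker values consistent with the
assigned subtype, clinical covariates, and recurrence times drawn from a
proportional-hazards model whose log hazard is linear in the dose-coded
(−1/0/+1) event states plus clinical terms.  Every random draw is recorded in
a :class:`TruthTable` so downstream stages (segmentation, marker selection,
risk grouping) can be tested for recovery of the planted structure.

Randomness is driven by a single seed expanded through
``numpy.random.SeedSequence.spawn`` into fixed per-stage streams
(subtypes, event draws, probe noise, markers/clinical, survival, censoring),
so each stage is reproducible in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "GenomeLayout",
    "PlantedEvent",
    "SimulationConfig",
    "TruthTable",
    "ProbeMatrix",
    "default_layout",
    "default_events",
    "default_config",
    "simulate_probe_matrix",
    "simulate_clinical",
    "simulate_survival",
    "simulate_cohort",
]

SUBTYPES = ("LUM A", "LUM B", "HER2", "TNBC")

# classified subtype counts in the source cohort (LUM A / LUM B / HER2 / TNBC),
# normalised to proportions over the classifiable samples
_SUBTYPE_COUNTS = np.array([389.0, 156.0, 158.0, 184.0])
DEFAULT_SUBTYPE_PROPS = dict(zip(SUBTYPES, _SUBTYPE_COUNTS / _SUBTYPE_COUNTS.sum()))


class ProbeMatrix:
    """Samples × ordered genomic probes on the linear copy-number scale.

    Parameters
    ----------
    probes : DataFrame with columns ``probe_id, chrom, pos`` sorted by
        (chrom, pos), positions 1-based and strictly increasing per chromosome.
    values : DataFrame indexed by sample id with one column per ``probe_id``.
    """

    def __init__(self, probes: pd.DataFrame, values: pd.DataFrame):
        probes = probes.reset_index(drop=True)
        required = {"probe_id", "chrom", "pos"}
        if not required.issubset(probes.columns):
            raise ValueError(f"probe table needs columns {sorted(required)}")
        for chrom, grp in probes.groupby("chrom", sort=False):
            d = np.diff(grp["pos"].to_numpy())
            if np.any(d <= 0):
                raise ValueError(
                    f"probe positions must be strictly increasing on {chrom}; "
                    "sort the table by (chrom, pos)")
        if list(values.columns) != list(probes["probe_id"]):
            raise ValueError("values columns must match probe_id order")
        if not np.all(np.isfinite(values.to_numpy())):
            raise ValueError("probe values must be finite")
        self.probes = probes
        self.values = values

    @property
    def samples(self):
        return list(self.values.index)

    @property
    def chromosomes(self):
        return list(dict.fromkeys(self.probes["chrom"]))

    def chromosome_values(self, chrom: str) -> pd.DataFrame:
        mask = (self.probes["chrom"] == chrom).to_numpy()
        return self.values.loc[:, mask]


@dataclass(frozen=True)
class GenomeLayout:
    """Chromosome sizes and evenly spaced probe coordinates."""

    chromosomes: tuple = (("chr1", 2500), ("chr2", 2500),
                          ("chr3", 2500), ("chr4", 2500))
    spacing: int = 10_000  # bp between consecutive probes

    def __post_init__(self):
        for name, n in self.chromosomes:
            if n < 50:
                raise ValueError(f"{name}: need ≥50 probes per chromosome, got {n}")

    @property
    def n_probes(self) -> int:
        return sum(n for _, n in self.chromosomes)

    def probe_table(self) -> pd.DataFrame:
        rows = []
        for name, n in self.chromosomes:
            pos = 1 + self.spacing * np.arange(n)
            rows.append(pd.DataFrame({
                "probe_id": [f"{name}_p{i:05d}" for i in range(n)],
                "chrom": name,
                "pos": pos,
            }))
        return pd.concat(rows, ignore_index=True)


@dataclass(frozen=True)
class PlantedEvent:
    """A contiguous gain or loss planted at subtype-dependent frequency."""

    name: str
    chrom: str
    start_probe: int  # inclusive, 0-based within chromosome
    stop_probe: int   # inclusive
    direction: str    # "gain" | "loss"
    magnitude: float = 1.0
    frequency: dict = field(default_factory=dict)  # subtype -> [0, 1]
    beta: float = 0.0  # log hazard per dose unit; 0 = non-prognostic

    def __post_init__(self):
        if self.direction not in ("gain", "loss"):
            raise ValueError("direction must be 'gain' or 'loss'")
        if self.start_probe > self.stop_probe:
            raise ValueError(f"{self.name}: start_probe > stop_probe")
        for st, f in self.frequency.items():
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"{self.name}: frequency for {st} outside [0,1]")

    def freq_for(self, subtype: str) -> float:
        return float(self.frequency.get(subtype, self.frequency.get("all", 0.0)))

    @property
    def sign(self) -> int:
        return 1 if self.direction == "gain" else -1


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for a synthetic cohort."""

    n_samples: int = 400
    subtype_props: dict = field(default_factory=lambda: dict(DEFAULT_SUBTYPE_PROPS))
    noise_sd: float = 0.15
    noise_df: float | None = None  # None = Gaussian; else Student-t df (FFPE-like tails)
    baseline_cn: float = 2.0
    events: tuple = ()
    # clinical covariate distributions (age in years; size / node as rates)
    age_mean: float = 54.4
    age_sd: float = 12.6
    p_size_ge2cm: float = 0.39
    p_node_positive: float = 0.40
    p_chemo: float = 0.45
    p_endocrine: float = 0.45
    # log-hazard for clinical terms
    beta_node: float = float(np.log(2.0))
    beta_size: float = float(np.log(1.2))
    beta_age_le50: float = float(np.log(1.1))
    # baseline hazard & censoring (time unit: months)
    # baseline rate calibrated so roughly 30% of samples recur inside the
    # 240-month horizon, matching the source cohort's training event fraction
    hazard_family: str = "exponential"  # or "weibull"
    hazard_scale: float = 500.0  # exponential: mean latent time in months
    hazard_shape: float = 1.0
    horizon_months: float = 240.0
    dropout_rate: float = 0.2
    seed: int = 0

    def __post_init__(self):
        total = sum(self.subtype_props.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"subtype proportions must sum to 1, got {total}")
        if self.noise_sd <= 0:
            raise ValueError("noise sd must be > 0")
        if self.hazard_scale <= 0:
            raise ValueError("hazard scale must be > 0")
        self._validate_events()

    def _validate_events(self):
        by_chrom: dict[str, list] = {}
        for ev in self.events:
            by_chrom.setdefault(ev.chrom, []).append(ev)
        for chrom, evs in by_chrom.items():
            evs = sorted(evs, key=lambda e: e.start_probe)
            for a, b in zip(evs, evs[1:]):
                if b.start_probe <= a.stop_probe:
                    raise ValueError(
                        f"planted events {a.name} and {b.name} overlap on {chrom}; "
                        "overlapping events make dose coding ambiguous")

    def streams(self):
        """Named per-stage random generators derived from the single seed."""
        names = ("subtype", "events", "noise", "clinical", "survival", "censoring")
        children = np.random.SeedSequence(self.seed).spawn(len(names))
        return {k: np.random.default_rng(s) for k, s in zip(names, children)}


class TruthTable:
    """Ground truth per sample: subtype, event doses, risk index, latent time."""

    def __init__(self, samples: pd.DataFrame, doses: pd.DataFrame):
        self.samples = samples  # sample, subtype, risk_index (+ true_time later)
        self.doses = doses      # samples × event names, entries in {-1, 0, +1}

    @property
    def sample_ids(self):
        return list(self.samples["sample"])


def default_events() -> tuple:
    """Twelve planted events on the default 4 × 2,500-probe genome.

    Six carry prognostic weight (|β| between 0.3 and 0.7, both signs), six are
    passengers; frequencies differ by subtype so the subtype-frequency tests
    have signal to find.
    """
    f = lambda a, b, h, t: {"LUM A": a, "LUM B": b, "HER2": h, "TNBC": t}
    return (
        PlantedEvent("ev01", "chr1", 100, 349, "gain", frequency=f(.30, .35, .30, .30), beta=0.6),
        PlantedEvent("ev02", "chr1", 700, 899, "loss", frequency=f(.10, .30, .15, .20), beta=0.45),
        PlantedEvent("ev03", "chr1", 1500, 1799, "gain", frequency=f(.20, .20, .20, .20), beta=0.0),
        PlantedEvent("ev04", "chr2", 200, 449, "loss", frequency=f(.15, .15, .15, .40), beta=0.5),
        PlantedEvent("ev05", "chr2", 1000, 1199, "gain", frequency=f(.25, .25, .45, .20), beta=-0.6),
        PlantedEvent("ev06", "chr2", 1900, 2099, "loss", frequency=f(.10, .10, .10, .10), beta=0.0),
        PlantedEvent("ev07", "chr3", 150, 399, "gain", frequency=f(.30, .30, .30, .30), beta=0.0),
        PlantedEvent("ev08", "chr3", 900, 1149, "loss", frequency=f(.20, .35, .20, .25), beta=0.7),
        PlantedEvent("ev09", "chr3", 1800, 1999, "gain", frequency=f(.15, .15, .15, .15), beta=0.0),
        PlantedEvent("ev10", "chr4", 300, 549, "loss", frequency=f(.12, .12, .12, .30), beta=-0.3),
        PlantedEvent("ev11", "chr4", 1200, 1449, "gain", frequency=f(.25, .25, .25, .25), beta=0.0),
        PlantedEvent("ev12", "chr4", 2000, 2199, "loss", frequency=f(.18, .18, .18, .18), beta=0.0),
    )


def default_layout() -> GenomeLayout:
    return GenomeLayout()


def default_config(n_samples: int = 400, seed: int = 0, **overrides) -> SimulationConfig:
    cfg = SimulationConfig(n_samples=n_samples, events=default_events(), seed=seed)
    return replace(cfg, **overrides) if overrides else cfg


def null_config(n_samples: int = 400, seed: int = 0, **overrides) -> SimulationConfig:
    """Signal-free conditions: planted events remain but carry no hazard.

    Every event β and every clinical log-hazard term is zero, so any risk
    score is pure noise and discrimination should sit at C = 0.5.
    """
    events = tuple(replace(ev, beta=0.0) for ev in default_events())
    cfg = SimulationConfig(n_samples=n_samples, events=events, seed=seed,
                           beta_node=0.0, beta_size=0.0, beta_age_le50=0.0)
    return replace(cfg, **overrides) if overrides else cfg


def _draw_subtypes(config, rng) -> np.ndarray:
    names = list(config.subtype_props)
    probs = np.array([config.subtype_props[k] for k in names])
    return rng.choice(names, size=config.n_samples, p=probs)


def simulate_probe_matrix(config: SimulationConfig,
                          layout: GenomeLayout) -> tuple[ProbeMatrix, TruthTable]:
    """Draw a probe-level copy-number matrix plus its ground-truth table.

    Each sample receives its subtype, then an independent Bernoulli draw per
    planted event at that subtype's frequency; carriers get ``baseline ±
    magnitude`` across the event span.  I.i.d. noise (Gaussian, or Student-t
    if ``noise_df`` is set) is added everywhere.
    """
    streams = config.streams()
    subtypes = _draw_subtypes(config, streams["subtype"])
    probes = layout.probe_table()
    n, m = config.n_samples, len(probes)
    sample_ids = [f"S{i:04d}" for i in range(n)]

    values = np.full((n, m), config.baseline_cn, dtype=float)
    chrom_offsets = {}
    off = 0
    for name, cnt in layout.chromosomes:
        chrom_offsets[name] = off
        off += cnt

    ev_rng = streams["events"]
    dose_cols = {}
    for ev in config.events:
        if ev.chrom not in chrom_offsets:
            raise ValueError(f"event {ev.name}: unknown chromosome {ev.chrom}")
        off = chrom_offsets[ev.chrom]
        freqs = np.array([ev.freq_for(s) for s in subtypes])
        carrier = ev_rng.random(n) < freqs
        dose = carrier.astype(int) * ev.sign
        sl = slice(off + ev.start_probe, off + ev.stop_probe + 1)
        values[:, sl] += dose[:, None] * ev.magnitude
        dose_cols[ev.name] = dose

    noise_rng = streams["noise"]
    if config.noise_df is None:
        values += noise_rng.normal(0.0, config.noise_sd, size=values.shape)
    else:
        values += config.noise_sd * noise_rng.standard_t(config.noise_df,
                                                         size=values.shape)

    doses = pd.DataFrame(dose_cols, index=sample_ids)
    betas = np.array([ev.beta for ev in config.events])
    risk = doses.to_numpy() @ betas if config.events else np.zeros(n)
    truth = TruthTable(
        pd.DataFrame({"sample": sample_ids, "subtype": subtypes,
                      "risk_index": risk}),
        doses,
    )
    pm = ProbeMatrix(probes, pd.DataFrame(values, index=sample_ids,
                                          columns=probes["probe_id"]))
    return pm, truth


def simulate_clinical(truth: TruthTable, config: SimulationConfig) -> pd.DataFrame:
    """Clinical covariates and marker panel consistent with each true subtype.

    Markers follow the classification rules used downstream: luminal tumours
    are ER+ with Ki67 split at 20% (LUM A below, LUM B at/above); HER2 tumours
    carry ERBB2 copy number above the 2.8 gain threshold; TNBC is ER−/PR− with
    unamplified ERBB2.  This makes subtype assignment round-trippable.
    """
    rng = config.streams()["clinical"]
    n = config.n_samples
    st = truth.samples["subtype"].to_numpy()

    age = rng.normal(config.age_mean, config.age_sd, n).clip(25, 90)
    size_ge2 = (rng.random(n) < config.p_size_ge2cm).astype(int)
    node_pos = (rng.random(n) < config.p_node_positive).astype(int)
    chemo = (rng.random(n) < config.p_chemo).astype(int)
    endocrine = (rng.random(n) < config.p_endocrine).astype(int)

    er = np.empty(n, dtype=object)
    pr = np.empty(n, dtype=object)
    ki67 = np.empty(n)
    erbb2 = np.empty(n)
    for i, s in enumerate(st):
        if s == "HER2":
            er[i] = "+" if rng.random() < 0.5 else "-"
            pr[i] = er[i]
            ki67[i] = rng.uniform(5, 60)
            erbb2[i] = rng.uniform(3.2, 8.0)
        elif s == "TNBC":
            er[i], pr[i] = "-", "-"
            ki67[i] = rng.uniform(10, 80)
            erbb2[i] = float(np.clip(rng.normal(2.0, 0.2), 1.2, 2.6))
        else:
            er[i] = "+"
            pr[i] = "+" if rng.random() < 0.8 else "-"
            ki67[i] = rng.uniform(1, 18) if s == "LUM A" else rng.uniform(22, 70)
            erbb2[i] = float(np.clip(rng.normal(2.0, 0.2), 1.2, 2.6))

    return pd.DataFrame({
        "sample": truth.sample_ids,
        "age": np.round(age, 1),
        "age_le50": (age <= 50).astype(int),
        "size_ge2cm": size_ge2,
        "node_positive": node_pos,
        "er": er, "pr": pr,
        "ki67_pct": np.round(ki67, 1),
        "erbb2_cn": np.round(erbb2, 3),
        "chemotherapy": chemo,
        "endocrine_therapy": endocrine,
    })


def simulate_survival(truth: TruthTable, clinical: pd.DataFrame,
                      config: SimulationConfig) -> pd.DataFrame:
    """Recurrence times from h(t) = h0(t)·exp(Σ β_j x_ij + γ'clinical).

    Inverse-transform sampling for exponential/Weibull baselines; censoring is
    the minimum of the administrative horizon and, with probability
    ``dropout_rate``, a uniform dropout time on (0, horizon).
    """
    if list(clinical["sample"]) != truth.sample_ids:
        raise ValueError("truth and clinical tables must align on sample IDs")
    streams = config.streams()
    rng, crng = streams["survival"], streams["censoring"]
    n = len(truth.sample_ids)

    lp = (truth.samples["risk_index"].to_numpy()
          + config.beta_node * clinical["node_positive"].to_numpy()
          + config.beta_size * clinical["size_ge2cm"].to_numpy()
          + config.beta_age_le50 * clinical["age_le50"].to_numpy())
    bad = ~np.isfinite(lp)
    if bad.any():
        sid = truth.sample_ids[int(np.flatnonzero(bad)[0])]
        raise ValueError(f"non-finite linear predictor for sample {sid}")

    e = rng.exponential(1.0, n)
    if config.hazard_family == "exponential":
        t_event = config.hazard_scale * e / np.exp(lp)
    elif config.hazard_family == "weibull":
        t_event = config.hazard_scale * (e / np.exp(lp)) ** (1.0 / config.hazard_shape)
    else:
        raise ValueError(f"unknown hazard family {config.hazard_family!r}")

    censor = np.full(n, config.horizon_months)
    dropout = crng.random(n) < config.dropout_rate
    censor[dropout] = crng.uniform(0, config.horizon_months, dropout.sum())
    time = np.minimum(t_event, censor)
    event = (t_event <= censor).astype(int)
    time = np.maximum(time, 1e-6)  # survival machinery needs strictly positive times

    truth.samples = truth.samples.assign(true_time=t_event)
    return pd.DataFrame({"sample": truth.sample_ids,
                         "time_months": time, "event": event})


def simulate_marker_cohort(n_samples: int = 728, n_segments: int = 150,
                           prognostic_betas=(0.7, -0.7, 0.65, -0.6, 0.5, 0.4),
                           carrier_freq: float = 0.30,
                           hazard_scale: float = 500.0,
                           horizon_months: float = 240.0,
                           dropout_rate: float = 0.2,
                           seed: int = 0):
    """Dose-matrix-level cohort for marker-selection experiments.

    Skips the probe/segmentation layers: draws a samples × segments dose
    matrix directly (each segment has a fixed direction and i.i.d. Bernoulli
    carriers at ``carrier_freq``), with the first ``len(prognostic_betas)``
    segments prognostic and the rest passengers, then exponential recurrence
    times from the dose-linear log hazard.  Returns ``(doses, outcome,
    true_betas)``.
    """
    ss = np.random.SeedSequence(seed).spawn(3)
    rng_d, rng_s, rng_c = (np.random.default_rng(s) for s in ss)
    signs = np.where(rng_d.random(n_segments) < 0.5, 1, -1)
    carrier = rng_d.random((n_samples, n_segments)) < carrier_freq
    doses = carrier.astype(int) * signs[None, :]
    betas = np.zeros(n_segments)
    betas[:len(prognostic_betas)] = prognostic_betas
    lp = doses @ betas
    t_event = hazard_scale * rng_s.exponential(1.0, n_samples) / np.exp(lp)
    censor = np.full(n_samples, horizon_months)
    drop = rng_c.random(n_samples) < dropout_rate
    censor[drop] = rng_c.uniform(0, horizon_months, drop.sum())
    sample_ids = [f"S{i:04d}" for i in range(n_samples)]
    seg_ids = [f"seg{j:04d}" for j in range(n_segments)]
    outcome = pd.DataFrame({
        "sample": sample_ids,
        "time_months": np.maximum(np.minimum(t_event, censor), 1e-6),
        "event": (t_event <= censor).astype(int),
    })
    return (pd.DataFrame(doses, index=sample_ids, columns=seg_ids),
            outcome, pd.Series(betas, index=seg_ids, name="true_beta"))


def simulate_cohort(config: SimulationConfig, layout: GenomeLayout | None = None):
    """One-call cohort: returns (probe matrix, truth, clinical, survival)."""
    layout = layout or default_layout()
    pm, truth = simulate_probe_matrix(config, layout)
    clinical = simulate_clinical(truth, config)
    survival = simulate_survival(truth, clinical, config)
    return pm, truth, clinical, survival
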