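"""Synthetic nCounter-like datasets with the study's design and known truth.

The generator emulates the biomarker study layout: 16 healthy individuals (HI)
sampled three times, 16 glioblastoma patients (GP) with survival follow-up, and
a 734-probe panel (654 human + 80 viral endogenous probes, 6 positive and 8
negative controls).  Expressed probes draw a log2 baseline abundance; subject
and replicate variance components are added on the log2 scale, group effects
(planted log2 fold changes) shift GP samples, a log-normal per-sample library
factor scales linear means, and counts are negative-binomial.  Negative
controls are low-mean counts independent of the library factor; positive
controls follow a fixed ladder times the library factor.  GP survival times are
exponential with a log-hazard linear in the z-scored latent expression of the
planted prognostic probes, with independent exponential censoring.

Noise defaults mirror the repeated-sampling observation that within-person
day-to-day variability exceeds between-person variability for circulating
miRNAs, with high counts and small overdispersion for detected probes as is
typical of the digital assay.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .panel_io import CountMatrix, classify_viral, load_fixtures, validate_sample_table

__all__ = [
    "SimConfigError",
    "SimConfig",
    "GroundTruth",
    "simulate_dataset",
    "table1_scenario",
    "prognostic_scenario",
    "null_scenario",
]

#: positive-control spike ladder (counts at library factor 1)
POS_LADDER = (32768, 8192, 2048, 512, 128, 32)

VIRAL_PANEL_SPLIT = {"ebv": 30, "hsv1": 15, "hsv2": 5, "kshv": 15, "hcmv": 15}


class SimConfigError(ValueError):
    pass


@dataclass
class SimConfig:
    """Study-design and noise parameters of the simulator.

    Variance components (``sigma_inter``, ``sigma_intra``) are log2-scale
    standard deviations; ``dispersion`` is the negative-binomial alpha in
    var = mu + alpha * mu^2; ``baseline_hazard`` is per month.
    """

    n_hi: int = 16
    n_replicates: int = 3
    n_gp: int = 16
    n_human_probes: int = 654
    n_viral_probes: int = 80
    n_pos_controls: int = 6
    n_neg_controls: int = 8
    n_expressed_human: int = 273
    n_expressed_viral: int = 11
    baseline_log_mean: float = 9.5
    baseline_log_sd: float = 1.2
    low_log_mean: float = 0.5
    low_log_sd: float = 0.5
    sigma_inter: float = 0.08
    sigma_intra: float = 0.20
    dispersion: float = 0.003
    lib_sigma: float = 0.2
    neg_mean: float = 10.0
    spike_table: dict[str, float] = field(default_factory=dict)
    prognostic_table: dict[str, float] = field(default_factory=dict)
    prognostic_factor_sd: float = 0.5
    baseline_hazard: float = 1.0 / 14.0
    censor_rate: float = 0.1
    seed: int | None = None
    human_probe_ids: list[str] | None = None
    viral_probe_ids: list[str] | None = None

    def __post_init__(self) -> None:
        for name in (
            "n_hi", "n_replicates", "n_gp", "n_human_probes", "n_viral_probes",
            "n_pos_controls", "n_neg_controls",
        ):
            if getattr(self, name) <= 0:
                raise SimConfigError(f"{name} must be positive")
        if self.sigma_inter < 0 or self.sigma_intra < 0:
            raise SimConfigError("variance components must be >= 0")
        if not (0 <= self.censor_rate < 1):
            raise SimConfigError("censor_rate must lie in [0, 1)")
        if self.dispersion < 0:
            raise SimConfigError("dispersion must be >= 0")


@dataclass
class GroundTruth:
    """Planted parameters for recovery checks."""

    true_logfc: pd.Series  # per endogenous probe, 0 where unspiked
    prognostic_effects: pd.Series  # log hazard ratio per z-score
    library_factors: pd.Series  # per sample
    expressed_ids: list[str]


def _build_panel(cfg: SimConfig) -> tuple[list[str], list[str]]:
    """Panel probe ids; planted ids are placed first so they are expressed."""
    planted = list(cfg.spike_table) + [
        p for p in cfg.prognostic_table if p not in cfg.spike_table
    ]
    planted_h = [p for p in planted if classify_viral(p)[0] == "human"]
    planted_v = [p for p in planted if classify_viral(p)[0] == "viral"]

    if cfg.human_probe_ids is not None:
        human = list(cfg.human_probe_ids)
        if missing := set(planted_h) - set(human):
            raise SimConfigError(f"spiked probes not in panel: {sorted(missing)}")
    else:
        taken = set(planted_h)
        human, i = list(planted_h), 0
        while len(human) < cfg.n_human_probes:
            i += 1
            if (name := f"hsa-miR-syn{i:04d}") not in taken:
                human.append(name)
    if cfg.viral_probe_ids is not None:
        viral = list(cfg.viral_probe_ids)
        if missing := set(planted_v) - set(viral):
            raise SimConfigError(f"spiked probes not in panel: {sorted(missing)}")
    else:
        viral = list(planted_v)
        per_prefix = dict(VIRAL_PANEL_SPLIT)
        for p in planted_v:
            prefix = classify_viral(p)[1]
            per_prefix[prefix] = per_prefix.get(prefix, 0) - 1
        taken_v = set(planted_v)
        for prefix, n in per_prefix.items():
            added, i = 0, 0
            while added < max(n, 0):
                i += 1
                if (name := f"{prefix}-miR-syn{i:02d}") not in taken_v:
                    viral.append(name)
                    added += 1
        viral = viral[: cfg.n_viral_probes]
    if len(human) != cfg.n_human_probes or len(viral) != cfg.n_viral_probes:
        raise SimConfigError("panel size inconsistent with probe id lists")
    return human, viral


def _nb_counts(rng: np.random.Generator, mu: np.ndarray, alpha: float) -> np.ndarray:
    if alpha <= 0:
        return rng.poisson(mu)
    n = 1.0 / alpha
    p = n / (n + mu)
    return rng.negative_binomial(n, p)


def simulate_dataset(
    cfg: SimConfig, seed: int | None = None
) -> tuple[CountMatrix, pd.DataFrame, GroundTruth]:
    """Generate (CountMatrix, sample table, GroundTruth); reproducible by seed."""
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    human, viral = _build_panel(cfg)
    endo_ids = human + viral
    pos_ids = [f"POS_{chr(65 + i)}" for i in range(cfg.n_pos_controls)]
    neg_ids = [f"NEG_{chr(65 + i)}" for i in range(cfg.n_neg_controls)]

    expressed = set(human[: cfg.n_expressed_human]) | set(
        viral[: cfg.n_expressed_viral]
    )
    n_endo = len(endo_ids)
    is_expr = np.array([p in expressed for p in endo_ids])
    baseline = np.where(
        is_expr,
        rng.normal(cfg.baseline_log_mean, cfg.baseline_log_sd, n_endo),
        rng.normal(cfg.low_log_mean, cfg.low_log_sd, n_endo),
    )
    spike = np.array([cfg.spike_table.get(p, 0.0) for p in endo_ids])

    # design ------------------------------------------------------------
    rows = []
    hi_ages = np.linspace(22, 58, cfg.n_hi)
    for i in range(cfg.n_hi):
        subject = f"HI{i + 1:02d}"
        for r in range(1, cfg.n_replicates + 1):
            rows.append(
                (f"{subject}-r{r}", subject, "HI", r, hi_ages[i],
                 "M" if i % 2 == 0 else "F", None, None, None)
            )
    gp_ages = np.linspace(35, 75, cfg.n_gp)
    for i in range(cfg.n_gp):
        subject = f"GP{i + 1:02d}"
        rows.append(
            (f"{subject}-r1", subject, "GP", 1, gp_ages[i],
             "M" if i % 2 == 0 else "F", None, None, None)
        )
    design = pd.DataFrame(
        rows,
        columns=[
            "sample_id", "subject_id", "group", "replicate_index",
            "age", "sex", "bmi", "survival_time", "event",
        ],
    )
    design["bmi"] = np.clip(rng.normal(24, 3, len(design)), 16, 40).round(1)

    subjects = design["subject_id"].unique()
    subj_effect = pd.DataFrame(
        rng.normal(0.0, cfg.sigma_inter, (n_endo, subjects.size)),
        index=endo_ids, columns=subjects,
    )
    # Planted prognostic miRNAs are modeled as co-expressed readouts of one
    # latent per-subject prognostic axis (e.g. tumor burden): each loads the
    # shared factor with log2-sd ``prognostic_factor_sd``.
    prog_mask = np.array([p in cfg.prognostic_table for p in endo_ids])
    prog_factor = pd.Series(rng.standard_normal(subjects.size), index=subjects)

    lib = pd.Series(
        rng.lognormal(0.0, cfg.lib_sigma, len(design)),
        index=design["sample_id"].to_numpy(),
    )

    # per-sample latent log2 mean and counts -----------------------------
    counts = np.empty((n_endo + len(pos_ids) + len(neg_ids), len(design)), dtype=np.int64)
    latent_by_sample = {}
    for j, row in enumerate(design.itertuples(index=False)):
        latent = baseline + subj_effect[row.subject_id].to_numpy()
        if prog_mask.any():
            latent = latent + cfg.prognostic_factor_sd * prog_factor[row.subject_id] * prog_mask
        if row.group == "GP":
            latent = latent + spike
        latent = latent + rng.normal(0.0, cfg.sigma_intra, n_endo)
        mu = np.exp2(latent) * lib[row.sample_id]
        counts[:n_endo, j] = _nb_counts(rng, mu, cfg.dispersion)
        latent_by_sample[row.sample_id] = latent
        pos_mu = np.asarray(POS_LADDER[: len(pos_ids)], dtype=float) * lib[row.sample_id]
        counts[n_endo : n_endo + len(pos_ids), j] = rng.poisson(pos_mu)
        counts[n_endo + len(pos_ids) :, j] = rng.poisson(
            cfg.neg_mean, len(neg_ids)
        )

    # survival -----------------------------------------------------------
    prog_ids = list(cfg.prognostic_table)
    gp_design = design[design["group"] == "GP"]
    if not gp_design.empty:
        gp_latent = np.array(
            [latent_by_sample[s][: n_endo] for s in gp_design["sample_id"]]
        )  # patients x probes
        loghaz = np.full(len(gp_design), np.log(cfg.baseline_hazard))
        for pid in prog_ids:
            col = endo_ids.index(pid)
            x = gp_latent[:, col]
            sd = x.std(ddof=1)
            z = (x - x.mean()) / sd if sd > 0 else np.zeros_like(x)
            loghaz = loghaz + cfg.prognostic_table[pid] * z
        rate = np.exp(loghaz)
        t_event = rng.exponential(1.0 / rate)
        if cfg.censor_rate > 0:
            c_rate = cfg.baseline_hazard * cfg.censor_rate / (1 - cfg.censor_rate)
            t_cens = rng.exponential(1.0 / c_rate, len(gp_design))
        else:
            t_cens = np.full(len(gp_design), np.inf)
        observed = np.minimum(t_event, t_cens)
        event = t_event <= t_cens
        design.loc[gp_design.index, "survival_time"] = np.round(observed, 3)
        design.loc[gp_design.index, "event"] = event

    probes = pd.DataFrame(
        [("endogenous", *classify_viral(p)) for p in endo_ids]
        + [("positive_control", "control", None)] * len(pos_ids)
        + [("negative_control", "control", None)] * len(neg_ids),
        columns=["probe_class", "species", "viral_prefix"],
        index=pd.Index(endo_ids + pos_ids + neg_ids, name="probe_id"),
    )
    matrix = CountMatrix(
        probes=probes,
        counts=pd.DataFrame(
            counts, index=probes.index, columns=design["sample_id"].to_numpy()
        ),
    )
    truth = GroundTruth(
        true_logfc=pd.Series(spike, index=endo_ids, name="true_logfc"),
        prognostic_effects=pd.Series(cfg.prognostic_table, dtype=float),
        library_factors=lib,
        expressed_ids=sorted(expressed),
    )
    return matrix, validate_sample_table(design), truth


# ---------------------------------------------------------------------------
# Presets
# ---------------------------------------------------------------------------

def table1_scenario(**overrides) -> SimConfig:
    """Preset planting the 19 published candidate logFC values.

    The panel expresses 284 probes (273 human + 11 viral, matching the study's
    analyzed count); the 19 planted probes carry their printed log2 fold
    changes and the remaining 265 expressed probes are null.
    """
    fixtures = load_fixtures()
    spikes = dict(zip(fixtures.table1["probe_id"], fixtures.table1["logfc"]))
    return SimConfig(spike_table=spikes, **overrides)


def prognostic_scenario(n_prognostic: int = 3, log_hr: float = 1.2, **overrides) -> SimConfig:
    """Preset planting survival effects on ``n_prognostic`` expressed probes.

    Each planted probe gets a log hazard ratio of ``log_hr`` per z-score of
    expression, on a months time scale.
    """
    effects = {
        f"hsa-miR-syn{i:04d}": log_hr for i in range(1, n_prognostic + 1)
    }
    return SimConfig(prognostic_table=effects, **overrides)


def null_scenario(**overrides) -> SimConfig:
    """No planted effects anywhere: group-null and survival-null."""
    return SimConfig(**overrides)
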