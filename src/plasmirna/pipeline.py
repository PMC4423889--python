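"""End-to-end orchestration: preprocess -> variability -> DE -> survival -> translation.

A run reads a count matrix and sample table (or simulates them from a preset),
executes every stage with the configured parameters, and writes per-stage TSV
outputs, a provenance log, and a summary JSON into a run directory.  Two runs
with identical inputs, parameters and seed produce identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from . import diffexpr, preprocess, survival, target_translation, variability
from .panel_io import check_samples_match, read_count_matrix, read_sample_table

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "ConfigError", "run_pipeline", "summarize"]

STAGES = (
    "preprocess", "variability", "diffexpr", "survival", "viral", "translation",
)


class ConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    """All stage parameters with study defaults.

    Thresholds default to the published protocol: detection filter at 0.8 of
    all samples, comparison filter at 0.2 per group, DE alpha 0.01 (adjusted),
    |logFC| >= 1 candidates, survival alpha 0.05 at six cutoff ratios, and a
    0.2 |logFC| prefilter before target translation.
    """

    counts_path: str | None = None
    samples_path: str | None = None
    targets_path: str | None = None
    gmt_path: str | None = None
    out_dir: str = "run"
    seed: int = 0
    normalization: str = "auto"  # auto | total_content | positive_control_sum | stable_set
    min_detect_frac: float = 0.8
    comparison_frac: float = 0.2
    de_alpha: float = 0.01
    min_abs_logfc: float = 1.0
    adjust: str = "bh"
    reference_min_age: float | None = 40.0
    survival_alpha: float = 0.05
    ratios: tuple[float, ...] = survival.DEFAULT_RATIOS
    translate_min_logfc: float = 0.2
    enrich_alpha: float = 0.05
    relieff_k: int = 10
    k_clusters: int = 6
    cluster_cutoff: float | None = None
    top_gene_count: int = 100

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - {f for f in cls.__dataclass_fields__}
        if unknown:
            raise ConfigError(f"unknown config keys {sorted(unknown)}")
        if "ratios" in data:
            data["ratios"] = tuple(data["ratios"])
        return cls(**data)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_tsv(frame: pd.DataFrame, path: Path, index: bool = True) -> None:
    frame.to_csv(path, sep="\t", index=index, lineterminator="\n")


def run_pipeline(cfg: RunConfig) -> Path:
    """Execute every stage; returns the run directory."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=logging.INFO)
    handler = logging.FileHandler(out / "run.log")
    logging.getLogger().addHandler(handler)
    summary: dict = {"stages": {}, "seed": cfg.seed, "version": __version__}
    try:
        if cfg.counts_path is None or cfg.samples_path is None:
            raise ConfigError("counts_path and samples_path are required")
        for label, p in (("counts", cfg.counts_path), ("samples", cfg.samples_path),
                         ("targets", cfg.targets_path), ("gmt", cfg.gmt_path)):
            if p is not None and not Path(p).exists():
                raise ConfigError(f"{label} file {p!r} does not exist")

        matrix = read_count_matrix(cfg.counts_path)
        design = read_sample_table(cfg.samples_path)
        check_samples_match(matrix, design)

        # --- preprocess -------------------------------------------------
        bg = preprocess.estimate_background(matrix)
        filtered, removed = preprocess.filter_nondetectable(
            matrix, bg, frac=cfg.min_detect_frac
        )
        if cfg.normalization == "auto":
            strategy, scores = preprocess.select_normalization(filtered, design, bg=bg)
        else:
            strategy, scores = cfg.normalization, {}
        norm = preprocess.normalize(filtered, strategy, bg=bg)
        _write_tsv(norm.values, out / "normalized.tsv")
        _write_tsv(removed, out / "removed_probes.tsv", index=False)
        summary["stages"]["preprocess"] = {
            "probes_in": int(matrix.n_probes),
            "probes_removed": int(len(removed)),
            "probes_analyzed": int(len(norm.endogenous_ids)),
            "strategy": strategy,
            "selection_scores": scores,
        }

        # --- variability -------------------------------------------------
        try:
            profile = variability.intra_inter_profile(
                norm, design, counts=filtered, bg=bg
            )
            _write_tsv(profile.intra, out / "cv_intra.tsv", index=False)
            _write_tsv(profile.inter.to_frame(), out / "cv_inter.tsv")
            summary["stages"]["variability"] = {
                "median_intra_cv": profile.pooled_median_intra(),
                "median_inter_cv": profile.median_inter(),
            }
        except ValueError as exc:
            summary["stages"]["variability"] = {"skipped": str(exc)}

        # --- differential expression -------------------------------------
        spec = diffexpr.ComparisonSpec(
            alpha=cfg.de_alpha,
            min_abs_logfc=cfg.min_abs_logfc,
            adjust=cfg.adjust,
            reference_min_age=cfg.reference_min_age,
        )
        comparable = preprocess.filter_for_comparison(
            filtered, bg, design, frac=cfg.comparison_frac
        )
        de = diffexpr.de_table(norm, design, spec, probe_ids=sorted(comparable))
        candidates = diffexpr.call_candidates(de, spec)
        _write_tsv(de, out / "de.tsv")
        _write_tsv(candidates, out / "candidates.tsv")
        summary["stages"]["diffexpr"] = {
            "probes_compared": int(len(de)),
            "significant": int((de["p_adj"] < spec.alpha).sum()),
            "candidates": int(len(candidates)),
        }

        # --- viral subset -------------------------------------------------
        viral, per_species = diffexpr.viral_differential(
            de[de["p_adj"] < spec.alpha]
        )
        _write_tsv(viral, out / "viral_de.tsv")
        summary["stages"]["viral"] = {
            "viral_differential": int(len(viral)),
            "per_species": {k: int(v) for k, v in per_species.items()},
        }

        # --- survival ------------------------------------------------------
        has_surv = design.loc[design["group"] == "GP", "survival_time"].notna().sum()
        if has_surv >= 4:
            scan = survival.prognostic_screen(
                norm, design, alpha=cfg.survival_alpha, ratios=cfg.ratios,
                probe_ids=sorted(comparable),
            )
            _write_tsv(scan, out / "survival_scan.tsv")
            prognostic = scan[scan["significant"]]
            overlap = survival.overlap_sets(candidates, prognostic)
            _write_tsv(overlap, out / "overlap.tsv")
            summary["stages"]["survival"] = {
                "prognostic": int(len(prognostic)),
                "prognostic_bh": int((scan["p_bh"] < cfg.survival_alpha).sum()),
                "overlap": int(len(overlap)),
            }
        else:
            summary["stages"]["survival"] = {"skipped": "insufficient survival data"}

        # --- translation ----------------------------------------------------
        if cfg.targets_path is not None:
            db = target_translation.read_targets_tsv(cfg.targets_path)
            ranked = target_translation.relieff_rank(
                norm, design, logfc=de["logfc"], k=cfg.relieff_k,
                probe_ids=list(de.index),
            )
            ranked = target_translation.prefilter_logfc(
                ranked, min_abs=cfg.translate_min_logfc
            )
            votes = target_translation.translate_votes(ranked, db)
            _write_tsv(votes, out / "votes.tsv")
            summary["stages"]["translation"] = {
                "ranked_mirnas": int(ranked.m_total),
                "voted_genes": int(len(votes)),
            }
            if cfg.gmt_path is not None:
                gene_sets = target_translation.read_gmt(cfg.gmt_path)
                universe = set(db["gene_id"])
                top = list(votes.index[: cfg.top_gene_count])
                rules, membership = target_translation.enrich_rules(
                    top, universe, gene_sets, alpha=cfg.enrich_alpha
                )
                _write_tsv(rules, out / "rules.tsv", index=False)
                summary["stages"]["translation"]["rules"] = int(len(rules))
                if len(membership) >= 2:
                    clustering = target_translation.cluster_rules(
                        membership,
                        cutoff_height=cfg.cluster_cutoff,
                        k=None if cfg.cluster_cutoff is not None else cfg.k_clusters,
                    )
                    (out / "clusters.json").write_text(
                        json.dumps(clustering.clusters(), indent=2, sort_keys=True)
                    )
                    summary["stages"]["translation"]["rule_clusters"] = (
                        clustering.n_clusters
                    )
                gene_hubs, mirna_hubs = target_translation.hub_report(
                    votes, ranked, db
                )
                _write_tsv(gene_hubs, out / "gene_hubs.tsv")
                _write_tsv(mirna_hubs, out / "mirna_hubs.tsv")
        else:
            summary["stages"]["translation"] = {"skipped": "no target database"}

        # --- provenance -----------------------------------------------------
        summary["parameters"] = {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in asdict(cfg).items()
        }
        summary["input_checksums"] = {
            label: _sha256(Path(p))
            for label, p in (("counts", cfg.counts_path), ("samples", cfg.samples_path))
            if p is not None
        }
        (out / "summary.json").write_text(
            json.dumps(summary, indent=2, sort_keys=True)
        )
        return out
    finally:
        logging.getLogger().removeHandler(handler)
        handler.close()


def summarize(run_dir: str | Path) -> dict:
    """Load and sanity-check a run's summary; marks missing stages."""
    run_dir = Path(run_dir)
    path = run_dir / "summary.json"
    if not path.exists():
        return {"incomplete": True, "missing": ["summary.json"]}
    summary = json.loads(path.read_text())
    missing = [s for s in STAGES if s not in summary.get("stages", {})]
    if missing:
        summary["missing_stages"] = missing
    return summary
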