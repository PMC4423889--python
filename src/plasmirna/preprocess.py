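"""Background estimation, detection filtering, and count normalization.

Digital hybridization counting reports a nonzero floor even for absent probes,
so a per-sample background is estimated from the negative-control probes
(mean + 2 sd, the conventional rule for this assay family).  Two detection
filters follow: a global one that discards endogenous probes below background
in at least 80% of all samples, and a per-comparison one that requires
detection in more than 80% of samples within *each* compared group.

Three normalization strategies are offered — total endogenous content,
positive-control sum, and a data-selected stable probe set — with a
replicate-CV-based selector that picks the strategy minimizing within-subject
variability, the only replicate structure the repeated-sampling design
provides.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .panel_io import CountMatrix

__all__ = [
    "ConfigurationError",
    "NormalizationError",
    "SelectionError",
    "BackgroundModel",
    "NormalizedMatrix",
    "STRATEGIES",
    "DEFAULT_EXCLUDED_PROBES",
    "estimate_background",
    "filter_nondetectable",
    "filter_for_comparison",
    "normalize",
    "select_normalization",
]

STRATEGIES = ("total_content", "positive_control_sum", "stable_set")

#: hsa-miR-720 was retired from miRBase as a likely tRNA fragment and is
#: dropped regardless of signal.
DEFAULT_EXCLUDED_PROBES = frozenset({"hsa-miR-720"})

STABLE_SET_SIZE = 50


class ConfigurationError(ValueError):
    pass


class NormalizationError(ValueError):
    pass


class SelectionError(ValueError):
    pass


@dataclass
class BackgroundModel:
    """Per-sample detection threshold derived from negative controls."""

    per_sample_threshold: pd.Series
    method: str = "neg_mean_plus_2sd"

    def __post_init__(self) -> None:
        if (self.per_sample_threshold < 0).any():
            raise ValueError("background thresholds must be nonnegative")


@dataclass
class NormalizedMatrix:
    """log2-scale expression with normalization provenance."""

    probes: pd.DataFrame
    values: pd.DataFrame  # log2(scaled count + 1), probes x samples
    strategy: str
    scale_factors: pd.Series = field(repr=False)

    def __post_init__(self) -> None:
        if self.strategy not in STRATEGIES:
            raise ValueError(f"unknown strategy {self.strategy!r}")
        if not np.isfinite(self.values.to_numpy()).all():
            raise ValueError("normalized values must be finite")
        if (self.scale_factors <= 0).any():
            raise ValueError("scale factors must be positive")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def endogenous_ids(self) -> pd.Index:
        return self.probes.index[self.probes["probe_class"] == "endogenous"]


def estimate_background(matrix: CountMatrix) -> BackgroundModel:
    """Per-sample threshold = mean + 2*sd (ddof=1) of negative-control counts."""
    neg = matrix.counts.loc[matrix.negative_control_ids]
    if len(neg) < 2:
        raise ConfigurationError(
            f"background estimation needs >=2 negative controls, found {len(neg)}"
        )
    thresholds = neg.mean(axis=0) + 2.0 * neg.std(axis=0, ddof=1)
    return BackgroundModel(per_sample_threshold=thresholds)


def filter_nondetectable(
    matrix: CountMatrix,
    bg: BackgroundModel,
    frac: float = 0.8,
    exclude: frozenset[str] | set[str] = DEFAULT_EXCLUDED_PROBES,
) -> tuple[CountMatrix, pd.DataFrame]:
    """Drop endogenous probes below background in >= ``frac`` of all samples.

    Returns the filtered matrix (controls always retained) and a report of
    removed probes with the reason (``nondetectable`` or ``excluded``).
    """
    if not (0 < frac <= 1):
        raise ValueError("frac must lie in (0, 1]")
    thresholds = bg.per_sample_threshold[matrix.sample_ids]
    endo = matrix.endogenous_ids
    below = matrix.counts.loc[endo].lt(thresholds, axis=1)
    below_frac = below.mean(axis=1)
    removed_nondet = set(below_frac.index[below_frac >= frac])
    removed_excl = (set(exclude) & set(endo)) - removed_nondet
    removed = removed_nondet | removed_excl
    keep = [p for p in matrix.probes.index if p not in removed]
    report = pd.DataFrame(
        {
            "probe_id": sorted(removed_nondet) + sorted(removed_excl),
            "reason": ["nondetectable"] * len(removed_nondet)
            + ["excluded"] * len(removed_excl),
        }
    )
    return matrix.subset_probes(keep), report


def filter_for_comparison(
    matrix: CountMatrix,
    bg: BackgroundModel,
    design: pd.DataFrame,
    frac: float = 0.2,
    group_col: str = "group",
) -> set[str]:
    """Probes detectable enough for a two-group comparison.

    Keeps endogenous probes whose below-background fraction is strictly less
    than ``frac`` within each group separately.
    """
    design = design[design["sample_id"].isin(matrix.sample_ids)]
    groups = design.groupby(group_col)["sample_id"].agg(list)
    if len(groups) != 2:
        raise ValueError(f"expected exactly two groups, found {len(groups)}")
    if any(len(s) < 2 for s in groups):
        raise ValueError("each group needs >=2 samples")
    endo = matrix.endogenous_ids
    keep = pd.Series(True, index=endo)
    for samples in groups:
        thr = bg.per_sample_threshold[samples]
        below = matrix.counts.loc[endo, samples].lt(thr, axis=1).mean(axis=1)
        keep &= below < frac
    return set(keep.index[keep])


def _strategy_totals(matrix: CountMatrix, strategy: str, stable_ids=None) -> pd.Series:
    if strategy == "total_content":
        ids = matrix.endogenous_ids
    elif strategy == "positive_control_sum":
        ids = matrix.positive_control_ids
    elif strategy == "stable_set":
        ids = stable_ids
    else:
        raise ValueError(f"unknown strategy {strategy!r}")
    if ids is None or len(ids) == 0:
        raise NormalizationError(f"no probes available for strategy {strategy!r}")
    return matrix.counts.loc[ids].sum(axis=0)


def _stable_probe_set(
    matrix: CountMatrix, bg: BackgroundModel, n: int = STABLE_SET_SIZE
) -> pd.Index:
    """Endogenous probes detected in every sample with lowest across-sample CV."""
    thr = bg.per_sample_threshold[matrix.sample_ids]
    endo = matrix.counts.loc[matrix.endogenous_ids]
    detected = endo.ge(thr, axis=1).all(axis=1)
    candidates = endo.loc[detected]
    if candidates.empty:
        raise NormalizationError("no probes detected in all samples for stable set")
    cv = candidates.std(axis=1, ddof=1) / candidates.mean(axis=1)
    return cv.nsmallest(min(n, len(cv))).index


def normalize(
    matrix: CountMatrix,
    strategy: str = "total_content",
    bg: BackgroundModel | None = None,
) -> NormalizedMatrix:
    """Scale each sample so its strategy total matches the across-sample mean.

    scale_factor_s = mean_t(total_t) / total_s; values = log2(count * factor + 1).
    """
    stable_ids = None
    if strategy == "stable_set":
        if bg is None:
            bg = estimate_background(matrix)
        stable_ids = _stable_probe_set(matrix, bg)
    totals = _strategy_totals(matrix, strategy, stable_ids)
    if (totals <= 0).any():
        bad = totals.index[totals <= 0][0]
        raise NormalizationError(f"zero per-sample total in sample {bad!r}")
    factors = totals.mean() / totals
    scaled = matrix.counts.mul(factors, axis=1)
    values = np.log2(scaled + 1.0)
    return NormalizedMatrix(
        probes=matrix.probes.copy(),
        values=values,
        strategy=strategy,
        scale_factors=factors,
    )


def _replicate_cv_score(norm: NormalizedMatrix, design: pd.DataFrame) -> float:
    """Median within-subject replicate CV (linear scale) across probes/subjects."""
    linear = np.exp2(norm.values.loc[norm.endogenous_ids]) - 1.0
    cvs = []
    for _, sub in design.groupby("subject_id"):
        samples = [s for s in sub["sample_id"] if s in linear.columns]
        if len(samples) < 2:
            continue
        block = linear[samples]
        mean = block.mean(axis=1)
        sd = block.std(axis=1, ddof=1)
        ok = mean > 0
        cvs.append((sd[ok] / mean[ok]).to_numpy())
    if not cvs:
        raise SelectionError("no subject with >=2 replicates")
    return float(np.median(np.concatenate(cvs)))


def select_normalization(
    matrix: CountMatrix,
    design: pd.DataFrame,
    bg: BackgroundModel | None = None,
) -> tuple[str, dict[str, float]]:
    """Pick the strategy minimizing median within-subject replicate CV.

    Ties resolve by the fixed preference order total_content,
    positive_control_sum, stable_set.
    """
    n_replicated = (design.groupby("subject_id")["sample_id"].count() >= 2).sum()
    if n_replicated < 2:
        raise SelectionError(
            "normalization selection needs >=2 subjects with >=2 replicates"
        )
    scores: dict[str, float] = {}
    for strategy in STRATEGIES:
        norm = normalize(matrix, strategy, bg=bg)
        scores[strategy] = _replicate_cv_score(norm, design)
    best = min(STRATEGIES, key=lambda s: scores[s])  # order-stable min
    return best, scores
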