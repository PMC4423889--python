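"""Group comparisons and the two-fold candidate rule.

Patients (GP) are compared against the age-matched healthy reference (HI older
than 40, "HIo") probe by probe with Welch's t-test on log2 normalized values,
Benjamini-Hochberg adjustment, and a candidate call requiring adjusted
p < 0.01 together with at least a two-fold difference (|logFC| >= 1, boundary
inclusive).  logFC is mean(GP) - mean(reference) on the log2 scale, so
down-in-patients probes carry negative values.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .panel_io import CountMatrix, classify_viral, load_fixtures
from .preprocess import BackgroundModel, NormalizedMatrix

__all__ = [
    "ComparisonSpec",
    "two_sample_t",
    "paired_t",
    "adjust_p",
    "compute_logfc",
    "de_table",
    "call_candidates",
    "subgroup_compare",
    "viral_differential",
]

MIN_P = float(np.nextafter(0, 1))  # reported for infinite-t degenerate cases


@dataclass
class ComparisonSpec:
    """Parameters of a two-group differential comparison."""

    test: str = "two_sample_t"
    alpha: float = 0.01
    min_abs_logfc: float = 1.0
    adjust: str = "bh"
    reference_min_age: float | None = 40.0
    collapse_replicates: bool = True

    def __post_init__(self) -> None:
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must lie in (0, 1)")
        if self.min_abs_logfc < 0:
            raise ValueError("min_abs_logfc must be >= 0")
        if self.test not in ("two_sample_t", "paired_t"):
            raise ValueError(f"unknown test {self.test!r}")


def _as_group(values, name: str) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1 or arr.size < 2:
        raise ValueError(f"group {name!r} needs >=2 values")
    if not np.isfinite(arr).all():
        raise ValueError(f"group {name!r} contains non-finite values")
    return arr


def two_sample_t(a, b) -> tuple[float, float]:
    """Welch's unequal-variance t with Welch-Satterthwaite df, two-sided."""
    a = _as_group(a, "a")
    b = _as_group(b, "b")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        return float(np.inf) * np.sign(a.mean() - b.mean()), MIN_P
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return float(t), float(p)


def paired_t(before, after) -> tuple[float, float]:
    """One-sample t on paired differences, two-sided."""
    before = _as_group(before, "before")
    after = _as_group(after, "after")
    if before.size != after.size:
        raise ValueError("paired groups must have equal length")
    diff = after - before
    if diff.std(ddof=1) == 0:
        if diff.mean() == 0:
            return 0.0, 1.0
        return float(np.inf) * np.sign(diff.mean()), MIN_P
    t, p = stats.ttest_rel(after, before)
    return float(t), float(p)


def adjust_p(p_raw: Sequence[float], method: str = "bh") -> np.ndarray:
    """Multiplicity adjustment; Benjamini-Hochberg step-up by default."""
    arr = np.asarray(p_raw, dtype=float)
    if arr.size == 0:
        return arr.copy()
    if ((arr < 0) | (arr > 1)).any() or not np.isfinite(arr).all():
        raise ValueError("p-values must lie in [0, 1]")
    method = method.lower()
    if method == "none":
        return arr.copy()
    mapping = {"bh": "fdr_bh", "bonferroni": "bonferroni"}
    if method not in mapping:
        raise ValueError(f"unknown adjustment {method!r}")
    return multipletests(arr, method=mapping[method])[1]


def _group_columns(
    norm: NormalizedMatrix, design: pd.DataFrame, spec: ComparisonSpec
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """GP and reference expression blocks (probes x observations).

    HI replicates collapse to per-subject means so subjects, not repeated
    samples, are the units of the between-group test.
    """
    design = design[design["sample_id"].isin(norm.sample_ids)]
    gp_samples = design.loc[design["group"] == "GP", "sample_id"].tolist()
    ref = design[design["group"] == "HI"]
    if spec.reference_min_age is not None:
        ref = ref[ref["age"] > spec.reference_min_age]
    if not gp_samples or ref.empty:
        raise ValueError("empty comparison group")
    values = norm.values
    gp_block = values[gp_samples]
    if spec.collapse_replicates:
        cols = {
            subj: values[list(sub["sample_id"])].mean(axis=1)
            for subj, sub in ref.groupby("subject_id")
        }
        ref_block = pd.DataFrame(cols)
    else:
        ref_block = values[ref["sample_id"].tolist()]
    return gp_block, ref_block


def compute_logfc(
    norm: NormalizedMatrix,
    design: pd.DataFrame,
    spec: ComparisonSpec | None = None,
) -> pd.Series:
    """Per-probe log2 fold change, GP mean minus reference mean."""
    spec = spec or ComparisonSpec()
    gp, ref = _group_columns(norm, design, spec)
    return (gp.mean(axis=1) - ref.mean(axis=1)).rename("logfc")


def de_table(
    norm: NormalizedMatrix,
    design: pd.DataFrame,
    spec: ComparisonSpec | None = None,
    probe_ids: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Full differential-expression table for the endogenous panel.

    Columns: probe_id (index), logfc, p_raw, p_adj, direction, candidate,
    species, gbm_known, blood_cell.  Annotation flags come from the packaged
    candidate-list fixture where the probe appears there.
    """
    spec = spec or ComparisonSpec()
    gp, ref = _group_columns(norm, design, spec)
    ids = pd.Index(probe_ids) if probe_ids is not None else norm.endogenous_ids
    gp_arr = gp.loc[ids].to_numpy()
    ref_arr = ref.loc[ids].to_numpy()
    if gp_arr.shape[1] < 2 or ref_arr.shape[1] < 2:
        raise ValueError("each group needs >=2 observations")
    t, p = stats.ttest_ind(gp_arr, ref_arr, axis=1, equal_var=False)
    # degenerate zero-variance probes: identical groups -> p=1
    nan = ~np.isfinite(p)
    if nan.any():
        equal = gp_arr.mean(axis=1) == ref_arr.mean(axis=1)
        p = np.where(nan & equal, 1.0, p)
        p = np.where(nan & ~equal, MIN_P, p)
        t = np.where(~np.isfinite(t) & equal, 0.0, t)
    logfc = gp_arr.mean(axis=1) - ref_arr.mean(axis=1)
    out = pd.DataFrame(
        {
            "logfc": logfc,
            "p_raw": p,
            "p_adj": adjust_p(p, spec.adjust),
            "direction": np.where(logfc >= 0, "up", "down"),
        },
        index=ids,
    )
    out["candidate"] = (out["p_adj"] < spec.alpha) & (
        out["logfc"].abs() >= spec.min_abs_logfc
    )
    out["species"] = norm.probes.loc[ids, "species"]
    fixtures = load_fixtures().table1.set_index("probe_id")
    out["gbm_known"] = [
        bool(fixtures.at[i, "gbm_known"]) if i in fixtures.index
        and fixtures.at[i, "gbm_known"] is not None
        and fixtures.at[i, "gbm_known"] == fixtures.at[i, "gbm_known"]
        else False
        for i in ids
    ]
    out["blood_cell"] = [
        bool(fixtures.at[i, "blood_cell"]) if i in fixtures.index else False
        for i in ids
    ]
    out.index.name = "probe_id"
    return out


def call_candidates(
    results: pd.DataFrame, spec: ComparisonSpec | None = None
) -> pd.DataFrame:
    """Subset to candidates (p_adj < alpha and |logFC| >= min), sorted by logFC."""
    spec = spec or ComparisonSpec()
    mask = (results["p_adj"] < spec.alpha) & (
        results["logfc"].abs() >= spec.min_abs_logfc
    )
    return results.loc[mask].sort_values("logfc", kind="stable")


_COVARIATE_SPLITS: dict[str, Callable[[pd.DataFrame], pd.Series]] = {
    "age40": lambda d: np.where(d["age"] < 40, "lo", np.where(d["age"] > 40, "hi", None)),
    "sex": lambda d: np.where(d["sex"] == "M", "lo", "hi"),
    "bmi24": lambda d: np.where(d["bmi"] <= 24, "lo", "hi"),
}


def subgroup_compare(
    norm: NormalizedMatrix,
    design: pd.DataFrame,
    covariate: str,
    alpha: float = 0.05,
    counts: CountMatrix | None = None,
    bg: BackgroundModel | None = None,
) -> pd.DataFrame:
    """Within-HI covariate split (age 40 / sex / BMI 24) at raw p < alpha.

    Raw p-values are compared to alpha without adjustment, mirroring how
    trend-level covariate findings are screened.  Probes where more than half
    the signals of either stratum fall below background are flagged
    ``near_detection_limit`` (needs ``counts`` and ``bg``).
    """
    if covariate not in _COVARIATE_SPLITS:
        raise ValueError(f"unknown covariate {covariate!r}")
    hi = design[(design["group"] == "HI") & design["sample_id"].isin(norm.sample_ids)]
    strata = pd.Series(_COVARIATE_SPLITS[covariate](hi), index=hi.index)
    lo = hi.loc[strata == "lo", "sample_id"].tolist()
    hi_s = hi.loc[strata == "hi", "sample_id"].tolist()
    if len(lo) < 2 or len(hi_s) < 2:
        raise ValueError("each covariate stratum needs >=2 samples")
    ids = norm.endogenous_ids
    a = norm.values.loc[ids, hi_s].to_numpy()
    b = norm.values.loc[ids, lo].to_numpy()
    t, p = stats.ttest_ind(a, b, axis=1, equal_var=False)
    p = np.where(np.isfinite(p), p, 1.0)
    logfc = a.mean(axis=1) - b.mean(axis=1)
    out = pd.DataFrame(
        {"logfc": logfc, "p_raw": p, "significant": p < alpha}, index=ids
    )
    if counts is not None and bg is not None:
        flags = []
        for stratum in (lo, hi_s):
            thr = bg.per_sample_threshold[stratum]
            below = counts.counts.loc[ids, stratum].lt(thr, axis=1).mean(axis=1)
            flags.append(below > 0.5)
        out["near_detection_limit"] = flags[0] | flags[1]
    out.index.name = "probe_id"
    return out


def viral_differential(results: pd.DataFrame) -> tuple[pd.DataFrame, pd.Series]:
    """Viral subset of a DE table plus per-species counts.

    Accepts any frame with a probe_id index and a ``species`` column (absent
    species is inferred from the id prefix).
    """
    out = results.copy()
    if "species" not in out.columns:
        classified = [classify_viral(i) for i in out.index]
        out["species"] = [c[0] for c in classified]
        out["viral_prefix"] = [c[1] for c in classified]
    if "viral_prefix" not in out.columns:
        out["viral_prefix"] = [
            classify_viral(i)[1] if s == "viral" else None
            for i, s in zip(out.index, out["species"])
        ]
    viral = out[out["species"] == "viral"].copy()
    counts = viral["viral_prefix"].value_counts()
    return viral, counts
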