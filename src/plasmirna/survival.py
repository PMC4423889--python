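"""Kaplan-Meier estimation, log-rank testing, and the six-ratio cutoff scan.

For each miRNA, patients are split into low/high expression groups at six
predetermined ratios (0.25:0.75 ... 0.75:0.25) and the split with the smallest
two-sided log-rank p-value is kept.  The minimum over ratios is an optimistic
("minP") statistic: no multiplicity correction is applied to the headline list,
matching common practice in optimal-cutoff biomarker screens, but a BH-adjusted
column is always co-emitted because the uncorrected scan inflates the
false-positive rate well above its nominal level.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .preprocess import NormalizedMatrix

__all__ = [
    "DEFAULT_RATIOS",
    "KMCurve",
    "CutoffScan",
    "km_estimate",
    "logrank_test",
    "restricted_mean_survival",
    "cutoff_scan",
    "prognostic_screen",
    "overlap_sets",
]

DEFAULT_RATIOS: tuple[float, ...] = (0.25, 0.35, 0.45, 0.55, 0.65, 0.75)


def _check_surv(times, events) -> tuple[np.ndarray, np.ndarray]:
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=bool)
    if t.size == 0:
        raise ValueError("empty survival input")
    if t.shape != e.shape:
        raise ValueError("times and events must align")
    if (t < 0).any():
        raise ValueError("survival times must be nonnegative")
    return t, e


@dataclass
class KMCurve:
    """Product-limit survival curve with Greenwood variance and 95% band.

    Arrays are aligned on the distinct event times; the curve starts at
    S(0) = 1 implicitly.
    """

    times: np.ndarray
    survival: np.ndarray
    greenwood_var: np.ndarray
    ci_lower: np.ndarray
    ci_upper: np.ndarray

    def at(self, t: float) -> float:
        """S(t): right-continuous step function value."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


def km_estimate(times, events, conf_level: float = 0.95) -> KMCurve:
    """Kaplan-Meier product-limit estimate with a log-minus-log 95% band."""
    t, e = _check_surv(times, events)
    order = np.argsort(t, kind="stable")
    t, e = t[order], e[order]
    event_times = np.unique(t[e])
    n = t.size
    surv, var_term, rows = 1.0, 0.0, []
    z = stats.norm.ppf(0.5 + conf_level / 2.0)
    for et in event_times:
        at_risk = int((t >= et).sum())
        d = int((e & (t == et)).sum())
        surv *= 1.0 - d / at_risk
        if at_risk > d:
            var_term += d / (at_risk * (at_risk - d))
        gvar = surv**2 * var_term
        if 0.0 < surv < 1.0:
            # log(-log S) transform keeps the band inside [0, 1]
            se_cll = math.sqrt(var_term) / abs(math.log(surv))
            lo = surv ** math.exp(z * se_cll)
            hi = surv ** math.exp(-z * se_cll)
        else:
            lo = hi = surv
        rows.append((et, surv, gvar, lo, hi))
    arr = np.array(rows, dtype=float).reshape(-1, 5)
    return KMCurve(
        times=arr[:, 0],
        survival=arr[:, 1],
        greenwood_var=arr[:, 2],
        ci_lower=arr[:, 3],
        ci_upper=arr[:, 4],
    )


def logrank_test(times_a, events_a, times_b, events_b) -> tuple[float, float]:
    """Two-group log-rank test; returns (chi-square, two-sided p, df=1).

    At each distinct event time the observed events in group A are compared
    with their hypergeometric expectation given the pooled risk sets.
    """
    ta, ea = _check_surv(times_a, events_a)
    tb, eb = _check_surv(times_b, events_b)
    if ea.sum() + eb.sum() == 0:
        raise ValueError("log-rank undefined with zero events")
    event_times = np.unique(np.concatenate([ta[ea], tb[eb]]))
    o_minus_e = 0.0
    var = 0.0
    for et in event_times:
        n1 = (ta >= et).sum()
        n2 = (tb >= et).sum()
        d1 = (ea & (ta == et)).sum()
        d2 = (eb & (tb == et)).sum()
        n, d = n1 + n2, d1 + d2
        if n == 0:
            continue
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (n2 / n) * (n - d) / (n - 1)
    if var == 0:
        return 0.0, 1.0
    chi2 = o_minus_e**2 / var
    return float(chi2), float(stats.chi2.sf(chi2, df=1))


def restricted_mean_survival(times, events, tau: float) -> float:
    """Area under the KM curve up to tau (restricted mean survival time)."""
    curve = km_estimate(times, events)
    grid = np.concatenate([[0.0], curve.times[curve.times <= tau], [tau]])
    surv = np.concatenate([[1.0], curve.survival[curve.times <= tau]])
    return float(np.sum(np.diff(grid) * surv))


@dataclass
class CutoffScan:
    """Result of the six-ratio expression-cutoff scan for one probe."""

    probe_id: str
    ratios: tuple[float, ...]
    p_per_ratio: dict[float, float]
    best_ratio: float
    best_p: float
    cut_value: float
    direction: str  # high_expr_longer | low_expr_longer


def cutoff_scan(
    values: pd.Series,
    times,
    events,
    ratios: tuple[float, ...] = DEFAULT_RATIOS,
    probe_id: str = "",
) -> CutoffScan:
    """Scan predetermined low:high split ratios for the best log-rank p.

    The low-expression group holds the ``floor(r*n + 0.5)`` patients with the
    lowest expression (ties broken by stable input order).  Splits that would
    empty a group are skipped.  Direction compares restricted-mean survival of
    the two groups at the best split.
    """
    vals = np.asarray(values, dtype=float)
    t, e = _check_surv(times, events)
    if vals.size != t.size:
        raise ValueError("expression and survival records must align")
    if vals.size < 4:
        raise ValueError("cutoff scan needs >=4 patients")
    if np.ptp(vals) == 0:
        raise ValueError("cutoff scan undefined for constant expression")
    order = np.argsort(vals, kind="stable")
    n = vals.size
    p_per_ratio: dict[float, float] = {}
    best = None
    for r in ratios:
        n_low = int(math.floor(r * n + 0.5))
        if n_low < 1 or n_low >= n:
            warnings.warn(f"ratio {r} leaves an empty group at n={n}; skipped")
            continue
        low = order[:n_low]
        high = order[n_low:]
        if e[low].sum() + e[high].sum() == 0:
            continue
        _, p = logrank_test(t[low], e[low], t[high], e[high])
        p_per_ratio[r] = p
        if best is None or p < best[1]:
            cut = 0.5 * (vals[order[n_low - 1]] + vals[order[n_low]])
            best = (r, p, cut, low, high)
    if best is None:
        raise ValueError("no valid split produced a log-rank test")
    r, p, cut, low, high = best
    tau = float(t.max())
    rmst_low = restricted_mean_survival(t[low], e[low], tau)
    rmst_high = restricted_mean_survival(t[high], e[high], tau)
    direction = "high_expr_longer" if rmst_high >= rmst_low else "low_expr_longer"
    return CutoffScan(
        probe_id=probe_id,
        ratios=tuple(ratios),
        p_per_ratio=p_per_ratio,
        best_ratio=r,
        best_p=p,
        cut_value=cut,
        direction=direction,
    )


def _gp_expression(
    norm: NormalizedMatrix, design: pd.DataFrame
) -> tuple[pd.DataFrame, np.ndarray, np.ndarray]:
    """One expression column per patient with survival follow-up."""
    gp = design[(design["group"] == "GP") & design["sample_id"].isin(norm.sample_ids)]
    gp = gp[gp["survival_time"].notna()]
    # one sample per patient: the lowest replicate index present
    gp = gp.sort_values(["subject_id", "replicate_index"], kind="stable")
    gp = gp.drop_duplicates("subject_id", keep="first")
    times = gp["survival_time"].to_numpy(dtype=float)
    events = gp["event"].astype("boolean").fillna(False).to_numpy(dtype=bool)
    expr = norm.values[gp["sample_id"].tolist()]
    return expr, times, events


def prognostic_screen(
    norm: NormalizedMatrix,
    design: pd.DataFrame,
    alpha: float = 0.05,
    ratios: tuple[float, ...] = DEFAULT_RATIOS,
    probe_ids=None,
) -> pd.DataFrame:
    """Cutoff scan per probe; flags best_p < alpha (uncorrected) and adds BH.

    The ``significant`` column mirrors the uncorrected screening practice; the
    co-emitted ``p_bh`` column is the honest multiplicity-aware view.
    """
    from .diffexpr import adjust_p  # local import to avoid cycle

    expr, times, events = _gp_expression(norm, design)
    if times.size < 4:
        raise ValueError("prognostic screen needs >=4 patients with survival data")
    ids = pd.Index(probe_ids) if probe_ids is not None else norm.endogenous_ids
    rows = []
    for pid in ids:
        vals = expr.loc[pid]
        if np.ptp(vals.to_numpy()) == 0:
            continue
        scan = cutoff_scan(vals, times, events, ratios=ratios, probe_id=pid)
        rows.append(
            {
                "probe_id": pid,
                "best_ratio": scan.best_ratio,
                "best_p": scan.best_p,
                "cut_value": scan.cut_value,
                "direction": scan.direction,
                **{f"p_{r}": p for r, p in scan.p_per_ratio.items()},
            }
        )
    out = pd.DataFrame(rows)
    if out.empty:
        return out
    out = out.set_index("probe_id")
    out["p_bh"] = adjust_p(out["best_p"].to_numpy())
    out["significant"] = out["best_p"] < alpha
    return out


def overlap_sets(
    diagnostic: pd.DataFrame | list,
    prognostic: pd.DataFrame | list,
) -> pd.DataFrame:
    """Intersection of diagnostic and prognostic probe sets with provenance.

    Inputs are id lists or frames indexed/keyed by probe_id; direction columns
    (``direction``) are carried through when present.
    """

    def _ids_and_dir(obj, col_name):
        if isinstance(obj, pd.DataFrame):
            ids = obj.index if obj.index.name == "probe_id" else obj["probe_id"]
            ids = pd.Index(ids)
            if "direction" in obj.columns:
                dirs = pd.Series(obj["direction"].to_numpy(), index=ids)
            else:
                dirs = pd.Series(index=ids, dtype=object)
            return ids, dirs.rename(col_name)
        ids = pd.Index(obj)
        return ids, pd.Series(index=ids, dtype=object, name=col_name)

    d_ids, d_dir = _ids_and_dir(diagnostic, "de_direction")
    p_ids, p_dir = _ids_and_dir(prognostic, "survival_direction")
    common = d_ids.intersection(p_ids)
    out = pd.DataFrame(
        {
            "de_direction": d_dir.reindex(common),
            "survival_direction": p_dir.reindex(common),
        }
    )
    out.index.name = "probe_id"
    return out


def plot_km(values: pd.Series, times, events, cut_value: float, path) -> None:
    """Two KM curves around a cutoff: red above, black below, shaded 95% bands."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    vals = np.asarray(values, dtype=float)
    t, e = _check_surv(times, events)
    fig, ax = plt.subplots(figsize=(4.5, 3.5))
    for mask, color, label in (
        (vals > cut_value, "red", "above cutoff"),
        (vals <= cut_value, "black", "below cutoff"),
    ):
        if mask.sum() == 0:
            continue
        curve = km_estimate(t[mask], e[mask])
        xs = np.concatenate([[0.0], np.repeat(curve.times, 2)])
        ys = np.concatenate([np.repeat(np.concatenate([[1.0], curve.survival]), 2)[:-1]])
        ax.plot(xs, ys, color=color, label=label)
        ax.fill_between(
            curve.times, curve.ci_lower, curve.ci_upper,
            step="post", color=color, alpha=0.15,
        )
    ax.set_xlabel("time (months)")
    ax.set_ylabel("survival probability")
    ax.set_ylim(0, 1.02)
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
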