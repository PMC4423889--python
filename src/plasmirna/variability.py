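"""Intra- vs inter-individual coefficient-of-variation profiling.

Repeated morning sampling of the same healthy subjects lets physiological
(within-person, between-day) variability be separated from between-person
variability.  CVs are computed on the linear expression scale (back-transform
``2**value - 1`` of the log2 normalized values): intra-individual CV per
(subject, probe) over that subject's replicates, inter-individual CV per probe
over subject means.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .panel_io import CountMatrix
from .preprocess import BackgroundModel, NormalizedMatrix

__all__ = ["CVProfile", "coefficient_of_variation", "intra_inter_profile"]


def coefficient_of_variation(values) -> float:
    """sd (ddof=1) over mean; requires >=2 values with positive mean."""
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1 or arr.size < 2:
        raise ValueError("CV needs at least two values")
    mean = arr.mean()
    if mean <= 0:
        raise ValueError("CV undefined for nonpositive mean")
    return float(arr.std(ddof=1) / mean)


@dataclass
class CVProfile:
    """Boxplot-ready CV summaries from a repeated-sampling design.

    intra : long frame (subject_id, probe_id, cv) over each subject's replicates
    inter : per-probe CV across subject means
    """

    intra: pd.DataFrame
    inter: pd.Series

    def per_subject_summary(self) -> pd.DataFrame:
        return (
            self.intra.groupby("subject_id")["cv"]
            .describe()[["count", "25%", "50%", "75%"]]
            .rename(columns={"25%": "q1", "50%": "median", "75%": "q3"})
        )

    def pooled_median_intra(self) -> float:
        return float(self.intra["cv"].median())

    def median_inter(self) -> float:
        return float(self.inter.median())


def intra_inter_profile(
    norm: NormalizedMatrix,
    design: pd.DataFrame,
    counts: CountMatrix | None = None,
    bg: BackgroundModel | None = None,
) -> CVProfile:
    """Intra- and inter-individual CV profile on the linear scale.

    When raw ``counts`` and a background model are supplied, a (subject, probe)
    pair is skipped for the intra CV if any replicate is below background —
    near-zero means make the ratio unstable.
    """
    design = design[design["sample_id"].isin(norm.sample_ids)]
    replicated = design.groupby("subject_id").filter(lambda s: len(s) >= 2)
    if replicated["subject_id"].nunique() < 2:
        raise ValueError("profile needs >=2 subjects with >=2 replicates")

    linear = np.exp2(norm.values.loc[norm.endogenous_ids]) - 1.0

    detected = None
    if counts is not None and bg is not None:
        thr = bg.per_sample_threshold[norm.sample_ids]
        detected = counts.counts.loc[norm.endogenous_ids, norm.sample_ids].ge(
            thr, axis=1
        )

    intra_rows = []
    subject_means = {}
    for subject, sub in replicated.groupby("subject_id"):
        samples = list(sub["sample_id"])
        block = linear[samples]
        subject_means[subject] = block.mean(axis=1)
        mean = block.mean(axis=1)
        sd = block.std(axis=1, ddof=1)
        ok = mean > 0
        if detected is not None:
            ok &= detected[samples].all(axis=1)
        cv = sd[ok] / mean[ok]
        intra_rows.append(
            pd.DataFrame(
                {"subject_id": subject, "probe_id": cv.index, "cv": cv.to_numpy()}
            )
        )
    intra = pd.concat(intra_rows, ignore_index=True)

    means = pd.DataFrame(subject_means)  # probes x subjects
    inter_mean = means.mean(axis=1)
    inter_sd = means.std(axis=1, ddof=1)
    ok = inter_mean > 0
    inter = (inter_sd[ok] / inter_mean[ok]).rename("cv")
    return CVProfile(intra=intra, inter=inter)


def plot_cv_boxplot(profile: CVProfile, path) -> None:
    """Per-subject intra-CV boxplots alongside the pooled inter-CV distribution."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    subjects = sorted(profile.intra["subject_id"].unique())
    data = [
        profile.intra.loc[profile.intra["subject_id"] == s, "cv"].to_numpy()
        for s in subjects
    ]
    data.append(profile.inter.to_numpy())
    labels = subjects + ["inter"]
    fig, ax = plt.subplots(figsize=(max(6, 0.5 * len(labels)), 4))
    ax.boxplot(data, tick_labels=labels, showfliers=False)
    ax.set_ylabel("coefficient of variation")
    ax.tick_params(axis="x", rotation=90)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
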