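"""miRNA-to-target translation and gene-set rule analysis.

A ranked miRNA list (ReliefF on the two-class expression matrix, pre-filtered
at |logFC| >= 0.2) is translated into a ranked gene list by voting: each miRNA
contributes a normalized rank score s(m) = (M - rank + 1)/M, weighted by the
interaction probability of the miRNA-gene edge when the target database
provides one (validated interactions without a probability count as 1).
Top-voted genes feed flat gene-set enrichment rules (one-sided Fisher exact,
BH-corrected), the retained rules are Ward-clustered on their binary
gene-membership vectors, and reverse inference decomposes any gene's score
back into its contributing miRNAs.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage

from .diffexpr import adjust_p
from .preprocess import NormalizedMatrix

__all__ = [
    "RankedMiRNAs",
    "RuleClustering",
    "read_targets_tsv",
    "read_gmt",
    "relieff_weights",
    "relieff_rank",
    "prefilter_logfc",
    "rank_score",
    "translate_votes",
    "enrich_rules",
    "cluster_rules",
    "reverse_infer",
    "hub_report",
]

logger = logging.getLogger(__name__)


@dataclass
class RankedMiRNAs:
    """miRNAs ordered by discriminative weight.

    ``entries`` columns: mirna_id, weight, rank (1..m_total, rank 1 largest
    weight, ties broken by id), logfc.
    """

    entries: pd.DataFrame

    def __post_init__(self) -> None:
        ranks = np.sort(self.entries["rank"].to_numpy())
        if not np.array_equal(ranks, np.arange(1, len(ranks) + 1)):
            raise ValueError("ranks must be 1..m_total without gaps")

    @property
    def m_total(self) -> int:
        return len(self.entries)


# ---------------------------------------------------------------------------
# I/O helpers
# ---------------------------------------------------------------------------

def read_targets_tsv(path: str | Path) -> pd.DataFrame:
    """Target database TSV: mirna_id, gene_id, probability (optional), source."""
    db = pd.read_csv(path, sep="\t", dtype={"mirna_id": str, "gene_id": str})
    required = {"mirna_id", "gene_id"}
    if missing := required - set(db.columns):
        raise ValueError(f"target database missing columns {sorted(missing)}")
    if "probability" not in db.columns:
        db["probability"] = np.nan
    if "source" not in db.columns:
        db["source"] = "validated"
    prob = db["probability"]
    if ((prob.dropna() <= 0) | (prob.dropna() > 1)).any():
        raise ValueError("probabilities must lie in (0, 1]")
    if db.duplicated(["mirna_id", "gene_id", "source"]).any():
        raise ValueError("duplicate (mirna_id, gene_id, source) rows")
    return db


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """GMT gene sets: name, description, genes... (tab-separated)."""
    sets: dict[str, set[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"malformed GMT line: {line[:50]!r}")
        sets[fields[0]] = {g for g in fields[2:] if g}
    return sets


# ---------------------------------------------------------------------------
# ReliefF
# ---------------------------------------------------------------------------

def relieff_weights(
    X: np.ndarray, labels: np.ndarray, k: int = 10
) -> np.ndarray:
    """ReliefF feature weights for a two-class sample-by-feature matrix.

    Features are min-max scaled; for every instance the k nearest hits (same
    class) and k nearest misses (other class) by Manhattan distance update each
    feature weight by +diff(misses) - diff(hits), averaged over m*k terms.
    Constant features receive weight exactly 0.
    """
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if classes.size != 2:
        raise ValueError("ReliefF here requires exactly two classes")
    m, n_feat = X.shape
    span = X.max(axis=0) - X.min(axis=0)
    nonconst = span > 0
    Xs = np.zeros_like(X)
    Xs[:, nonconst] = (X[:, nonconst] - X.min(axis=0)[nonconst]) / span[nonconst]

    min_class = min(int((labels == c).sum()) for c in classes)
    if k > min_class - 1:
        k_eff = max(1, min_class - 1)
        warnings.warn(f"reducing ReliefF neighbors from {k} to {k_eff}")
        k = k_eff

    dist = np.abs(Xs[:, None, :] - Xs[None, :, :]).sum(axis=2)
    np.fill_diagonal(dist, np.inf)
    weights = np.zeros(n_feat)
    for i in range(m):
        same = labels == labels[i]
        hits = np.where(same)[0]
        hits = hits[hits != i]
        misses = np.where(~same)[0]
        hit_idx = hits[np.argsort(dist[i, hits], kind="stable")[:k]]
        miss_idx = misses[np.argsort(dist[i, misses], kind="stable")[:k]]
        weights += np.abs(Xs[miss_idx] - Xs[i]).sum(axis=0)
        weights -= np.abs(Xs[hit_idx] - Xs[i]).sum(axis=0)
    return weights / (m * k)


def relieff_rank(
    norm: NormalizedMatrix,
    design: pd.DataFrame,
    logfc: pd.Series,
    k: int = 10,
    label_col: str = "group",
    probe_ids=None,
) -> RankedMiRNAs:
    """Rank endogenous miRNAs by ReliefF weight between the two design groups."""
    design = design[design["sample_id"].isin(norm.sample_ids)]
    ids = pd.Index(probe_ids) if probe_ids is not None else norm.endogenous_ids
    X = norm.values.loc[ids, design["sample_id"].tolist()].to_numpy().T
    weights = relieff_weights(X, design[label_col].to_numpy(), k=k)
    entries = pd.DataFrame(
        {"mirna_id": ids, "weight": weights, "logfc": logfc.reindex(ids).to_numpy()}
    )
    entries = entries.sort_values(
        ["weight", "mirna_id"], ascending=[False, True], kind="stable"
    ).reset_index(drop=True)
    entries["rank"] = np.arange(1, len(entries) + 1)
    return RankedMiRNAs(entries=entries[["mirna_id", "weight", "rank", "logfc"]])


def prefilter_logfc(ranked: RankedMiRNAs, min_abs: float = 0.2) -> RankedMiRNAs:
    """Drop miRNAs with |logFC| strictly below ``min_abs``; re-compact ranks."""
    kept = ranked.entries[ranked.entries["logfc"].abs() >= min_abs].copy()
    kept = kept.sort_values("rank", kind="stable").reset_index(drop=True)
    kept["rank"] = np.arange(1, len(kept) + 1)
    return RankedMiRNAs(entries=kept)


# ---------------------------------------------------------------------------
# Vote translation
# ---------------------------------------------------------------------------

def rank_score(rank: int, m_total: int) -> float:
    """Normalized descending rank score s = (M - rank + 1) / M in (0, 1]."""
    return (m_total - rank + 1) / m_total


def _contributions(ranked: RankedMiRNAs, db: pd.DataFrame) -> pd.DataFrame:
    if ranked.m_total == 0:
        raise ValueError("empty ranked miRNA list")
    if db.empty:
        raise ValueError("empty target database")
    entries = ranked.entries.copy()
    entries["score"] = [
        rank_score(r, ranked.m_total) for r in entries["rank"]
    ]
    missing = set(entries["mirna_id"]) - set(db["mirna_id"])
    if missing:
        logger.info("%d ranked miRNAs absent from target DB", len(missing))
    merged = db.merge(entries[["mirna_id", "score"]], on="mirna_id", how="inner")
    merged["probability"] = merged["probability"].fillna(1.0)
    merged["contribution"] = merged["score"] * merged["probability"]
    return merged


def translate_votes(ranked: RankedMiRNAs, db: pd.DataFrame) -> pd.DataFrame:
    """Aggregate rank-score votes onto target genes.

    Returns a frame indexed by gene_id with ``score`` (sum of contributions)
    and ``n_mirnas`` (distinct contributing miRNAs), ordered by descending
    score with deterministic gene-id tie-break.
    """
    contrib = _contributions(ranked, db)
    # fsum: correctly-rounded, order-independent, so reverse inference re-sums
    # to the forward score bit-exactly
    votes = contrib.groupby("gene_id").agg(
        score=("contribution", lambda s: math.fsum(s)),
        n_mirnas=("mirna_id", "nunique"),
    )
    votes = votes.sort_values(
        ["score", "gene_id"], ascending=[False, True], kind="stable"
    )
    return votes


def reverse_infer(
    gene_id: str, ranked: RankedMiRNAs, db: pd.DataFrame
) -> pd.DataFrame:
    """Contributors to one gene's vote score, descending by contribution."""
    if gene_id not in set(db["gene_id"]):
        raise KeyError(f"gene {gene_id!r} absent from target database")
    contrib = _contributions(ranked, db)
    sub = contrib[contrib["gene_id"] == gene_id]
    return (
        sub[["mirna_id", "score", "probability", "contribution"]]
        .sort_values(
            ["contribution", "mirna_id"], ascending=[False, True], kind="stable"
        )
        .reset_index(drop=True)
    )


# ---------------------------------------------------------------------------
# Enrichment rules and clustering
# ---------------------------------------------------------------------------

def enrich_rules(
    top_genes: Iterable[str],
    universe: Iterable[str],
    gene_sets: Mapping[str, set[str]],
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """One-sided Fisher enrichment of ``top_genes`` in each gene set.

    Returns (rules, membership): rules with raw and BH-corrected p retained at
    p_corrected <= alpha; membership is the binary rule-by-gene matrix over the
    union of overlap genes of retained rules (the clustering feature space).
    """
    top = set(top_genes)
    uni = set(universe)
    if not top:
        raise ValueError("empty top gene list")
    if not top <= uni:
        raise ValueError("top_genes must be a subset of the universe")
    if not gene_sets:
        raise ValueError("no gene sets supplied")
    N, n_draw = len(uni), len(top)
    rows = []
    for name, members in gene_sets.items():
        in_uni = members & uni
        overlap = in_uni & top
        K = len(in_uni)
        if K == 0:
            continue
        # P(X >= |overlap|) under hypergeometric sampling of the top list
        p = float(stats.hypergeom.sf(len(overlap) - 1, N, K, n_draw))
        rows.append((name, sorted(overlap), p))
    if not rows:
        return pd.DataFrame(), pd.DataFrame()
    rules = pd.DataFrame(rows, columns=["set_name", "overlap_genes", "p_raw"])
    rules["p_corrected"] = adjust_p(rules["p_raw"].to_numpy())
    rules = rules[rules["p_corrected"] <= alpha].reset_index(drop=True)
    if rules.empty:
        return rules, pd.DataFrame()
    gene_union = sorted(set().union(*rules["overlap_genes"]))
    membership = pd.DataFrame(
        [
            [1 if g in set(ov) else 0 for g in gene_union]
            for ov in rules["overlap_genes"]
        ],
        index=rules["set_name"],
        columns=gene_union,
    )
    return rules, membership


@dataclass
class RuleClustering:
    """Ward hierarchy over rule membership vectors plus a flat partition."""

    linkage_matrix: np.ndarray
    labels: pd.Series  # rule name -> cluster id
    cutoff_height: float | None
    n_clusters: int

    def clusters(self) -> dict[int, list[str]]:
        return {
            int(c): sorted(self.labels.index[self.labels == c])
            for c in np.unique(self.labels)
        }


def cluster_rules(
    membership: pd.DataFrame,
    cutoff_height: float | None = None,
    k: int | None = None,
) -> RuleClustering:
    """Agglomerative Ward clustering of rules on Euclidean membership distance.

    Cut either at an absolute ``cutoff_height`` or into ``k`` clusters
    (exactly one must be given).
    """
    if len(membership) < 2:
        raise ValueError("clustering needs >=2 rules")
    if (cutoff_height is None) == (k is None):
        raise ValueError("give exactly one of cutoff_height or k")
    Z = linkage(membership.to_numpy(dtype=float), method="ward")
    if not np.all(np.diff(Z[:, 2]) >= -1e-9):
        raise AssertionError("Ward merge heights must be non-decreasing")
    if cutoff_height is not None:
        flat = fcluster(Z, t=cutoff_height, criterion="distance")
    else:
        flat = fcluster(Z, t=k, criterion="maxclust")
    labels = pd.Series(flat, index=membership.index, name="cluster")
    return RuleClustering(
        linkage_matrix=Z,
        labels=labels,
        cutoff_height=cutoff_height,
        n_clusters=int(labels.nunique()),
    )


# ---------------------------------------------------------------------------
# Hubs
# ---------------------------------------------------------------------------

def hub_report(
    votes: pd.DataFrame,
    ranked: RankedMiRNAs,
    db: pd.DataFrame,
    min_degree: int = 10,
    universe: Iterable[str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Gene hubs (most distinct contributing miRNAs) and miRNA hubs.

    miRNA hubs target at least ``min_degree`` genes within the analyzed
    universe (default: all genes in the vote table).
    """
    if votes.empty:
        return pd.DataFrame(), pd.DataFrame()
    gene_hubs = votes.sort_values(
        ["n_mirnas", "score"], ascending=[False, False], kind="stable"
    )[["n_mirnas", "score"]]
    uni = set(universe) if universe is not None else set(votes.index)
    ranked_ids = set(ranked.entries["mirna_id"])
    edges = db[db["mirna_id"].isin(ranked_ids) & db["gene_id"].isin(uni)]
    degree = edges.groupby("mirna_id")["gene_id"].nunique().rename("n_genes")
    mirna_hubs = (
        degree[degree >= min_degree]
        .sort_values(ascending=False, kind="stable")
        .to_frame()
    )
    return gene_hubs, mirna_hubs
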