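import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from plasmirna import target_translation as tt


def ranked_from(entries):
    """RankedMiRNAs from (mirna_id, rank, logfc) triples; weight from rank."""
    frame = pd.DataFrame(entries, columns=["mirna_id", "rank", "logfc"])
    frame["weight"] = 1.0 / frame["rank"]
    return tt.RankedMiRNAs(entries=frame[["mirna_id", "weight", "rank", "logfc"]])


def db_from(rows):
    frame = pd.DataFrame(rows, columns=["mirna_id", "gene_id", "probability"])
    frame["source"] = "validated"
    return frame


class TestReliefF:
    def test_constant_feature_gets_zero_weight(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((20, 4))
        X[:, 2] = 7.0
        w = tt.relieff_weights(X, np.repeat([0, 1], 10), k=3)
        assert w[2] == 0.0

    def test_duplicated_feature_gets_equal_weight(self):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((20, 3))
        X = np.column_stack([X, X[:, 0]])
        w = tt.relieff_weights(X, np.repeat([0, 1], 10), k=3)
        assert w[0] == pytest.approx(w[3], rel=1e-12)

    def test_affine_rescaling_invariance(self):
        rng = np.random.default_rng(2)
        X = rng.standard_normal((16, 5))
        labels = np.repeat([0, 1], 8)
        w1 = tt.relieff_weights(X, labels, k=3)
        X2 = X.copy()
        X2[:, 1] = 100.0 * X2[:, 1] - 7.0
        w2 = tt.relieff_weights(X2, labels, k=3)
        np.testing.assert_allclose(w1, w2, rtol=1e-10)

    def test_perfect_separator_ranks_first(self):
        hits = 0
        n_runs = 50
        for seed in range(n_runs):
            rng = np.random.default_rng(seed)
            X = rng.standard_normal((20, 10))
            labels = np.repeat([0, 1], 10)
            X[:, 4] = labels * 4.0 + rng.normal(0, 0.05, 20)
            w = tt.relieff_weights(X, labels, k=5)
            hits += np.argmax(w) == 4
        assert hits / n_runs >= 0.99

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            tt.relieff_weights(np.zeros((4, 2)), np.zeros(4), k=1)

    def test_neighbor_count_autoreduced(self):
        X = np.random.default_rng(3).standard_normal((6, 3))
        with pytest.warns(UserWarning, match="reducing"):
            tt.relieff_weights(X, np.repeat([0, 1], 3), k=10)


class TestPrefilter:
    def test_boundary_is_strict_below(self):
        ranked = ranked_from(
            [("m1", 1, 0.1), ("m2", 2, -0.2), ("m3", 3, 0.5)]
        )
        out = tt.prefilter_logfc(ranked, min_abs=0.2)
        assert list(out.entries["mirna_id"]) == ["m2", "m3"]
        assert list(out.entries["rank"]) == [1, 2]  # re-compacted

    def test_all_removed_gives_empty_and_downstream_rejects(self):
        ranked = ranked_from([("m1", 1, 0.0)])
        out = tt.prefilter_logfc(ranked)
        assert out.m_total == 0
        with pytest.raises(ValueError):
            tt.translate_votes(out, db_from([("m1", "G1", np.nan)]))


class TestVoting:
    def test_single_mirna_single_target(self):
        ranked = ranked_from([("m1", 1, 1.0)])
        votes = tt.translate_votes(ranked, db_from([("m1", "G1", np.nan)]))
        assert votes.loc["G1", "score"] == 1.0

    def test_two_mirnas_same_gene(self):
        ranked = ranked_from([("m1", 1, 1.0), ("m2", 2, 1.0)])
        db = db_from([("m1", "G1", 1.0), ("m2", "G1", 1.0)])
        votes = tt.translate_votes(ranked, db)
        assert votes.loc["G1", "score"] == pytest.approx(1.5)

    def test_probability_scales_contribution(self):
        ranked = ranked_from([("m1", 1, 1.0)])
        votes = tt.translate_votes(ranked, db_from([("m1", "G1", 0.5)]))
        assert votes.loc["G1", "score"] == pytest.approx(0.5)

    def test_missing_mirna_contributes_nothing(self):
        ranked = ranked_from([("m1", 1, 1.0), ("m2", 2, 1.0)])
        votes = tt.translate_votes(ranked, db_from([("m1", "G1", np.nan)]))
        assert votes.loc["G1", "score"] == 1.0

    def test_vote_conservation(self):
        rng = np.random.default_rng(4)
        mirnas = [f"m{i}" for i in range(1, 9)]
        ranked = ranked_from(
            [(m, i + 1, 1.0) for i, m in enumerate(mirnas)]
        )
        rows = [
            (m, f"G{g}", rng.choice([np.nan, 0.3, 0.8]))
            for m in mirnas
            for g in rng.choice(20, size=5, replace=False)
        ]
        db = db_from(rows)
        votes = tt.translate_votes(ranked, db)
        edges = db.copy()
        edges["prob"] = edges["probability"].fillna(1.0)
        s = {
            m: tt.rank_score(i + 1, len(mirnas)) for i, m in enumerate(mirnas)
        }
        total_edges = sum(
            s[r.mirna_id] * r.prob for r in edges.itertuples()
        )
        assert votes["score"].sum() == pytest.approx(total_edges, rel=1e-12)

    def test_db_row_order_invariance(self):
        ranked = ranked_from([("m1", 1, 1.0), ("m2", 2, 1.0)])
        db = db_from([("m1", "G1", 1.0), ("m2", "G1", 0.5), ("m2", "G2", np.nan)])
        v1 = tt.translate_votes(ranked, db)
        v2 = tt.translate_votes(ranked, db.iloc[::-1].reset_index(drop=True))
        pd.testing.assert_frame_equal(v1, v2)


class TestReverseInference:
    def test_single_contributor_identity(self):
        ranked = ranked_from([("m1", 1, 1.0)])
        db = db_from([("m1", "G1", np.nan)])
        contrib = tt.reverse_infer("G1", ranked, db)
        assert list(contrib["mirna_id"]) == ["m1"]
        assert contrib["contribution"].iloc[0] == 1.0

    def test_probability_orders_equal_rank_scores(self):
        ranked = ranked_from([("m1", 1, 1.0), ("m2", 2, 1.0)])
        db = db_from([("m1", "G1", 0.5), ("m2", "G1", 1.0)])
        contrib = tt.reverse_infer("G1", ranked, db)
        assert list(contrib["mirna_id"]) == ["m1", "m2"]  # 0.5 vs 0.5: id tie-break
        db2 = db_from([("m1", "G1", 0.4), ("m2", "G1", 1.0)])
        contrib2 = tt.reverse_infer("G1", ranked, db2)
        assert contrib2["mirna_id"].iloc[0] == "m2"

    def test_resummation_matches_forward_score_exactly(self):
        rng = np.random.default_rng(5)
        ranked = ranked_from([(f"m{i}", i, 1.0) for i in range(1, 7)])
        db = db_from(
            [(f"m{i}", "G1", p) for i, p in zip(range(1, 7), rng.random(6))]
        )
        votes = tt.translate_votes(ranked, db)
        contrib = tt.reverse_infer("G1", ranked, db)
        assert math.fsum(contrib["contribution"]) == votes.loc["G1", "score"]

    def test_absent_gene_rejected(self):
        ranked = ranked_from([("m1", 1, 1.0)])
        with pytest.raises(KeyError):
            tt.reverse_infer("G9", ranked, db_from([("m1", "G1", np.nan)]))


class TestEnrichment:
    def test_hypergeometric_oracle(self):
        """p for a set identical to the top list matches direct enumeration."""
        universe = [f"G{i}" for i in range(20)]
        top = universe[:5]
        sets = {"match": set(top), "half": set(universe[10:])}
        rules, membership = tt.enrich_rules(top, universe, sets, alpha=1.0)
        p_match = rules.set_index("set_name").loc["match", "p_raw"]
        # P(X >= 5) drawing 5 from 20 with 5 marked = 1 / C(20,5)
        assert p_match == pytest.approx(1 / 15504, rel=1e-10)
        assert p_match == pytest.approx(
            stats.hypergeom.sf(4, 20, 5, 5), rel=1e-12
        )
        assert set(membership.columns) >= set(top)

    def test_disjoint_set_dropped(self):
        universe = [f"G{i}" for i in range(10)]
        rules, _ = tt.enrich_rules(
            universe[:3], universe, {"other": set(universe[5:])}, alpha=0.05
        )
        assert rules.empty

    def test_universe_equal_to_top_is_undiscriminating(self):
        genes = ["G1", "G2", "G3"]
        rules, _ = tt.enrich_rules(genes, genes, {"s": {"G1", "G2"}}, alpha=0.05)
        assert rules.empty

    def test_top_outside_universe_rejected(self):
        with pytest.raises(ValueError):
            tt.enrich_rules(["X"], ["G1"], {"s": {"G1"}})


class TestClustering:
    def _membership(self, rows, n_genes=6):
        return pd.DataFrame(
            rows, index=[f"r{i}" for i in range(len(rows))],
            columns=[f"G{i}" for i in range(n_genes)],
        )

    def test_identical_vectors_one_cluster(self):
        m = self._membership([[1, 0, 1, 0, 0, 0]] * 3)
        out = tt.cluster_rules(m, cutoff_height=0.5)
        assert out.n_clusters == 1

    def test_two_blocks_recovered(self):
        m = self._membership(
            [[1, 1, 1, 0, 0, 0]] * 3 + [[0, 0, 0, 1, 1, 1]] * 3
        )
        out = tt.cluster_rules(m, k=2)
        labels = out.labels
        assert labels.iloc[:3].nunique() == 1
        assert labels.iloc[3:].nunique() == 1
        assert labels.iloc[0] != labels.iloc[-1]

    def test_cutoff_below_first_merge_gives_singletons(self):
        m = self._membership([[1, 0, 0, 0, 0, 0], [0, 1, 0, 0, 0, 0], [0, 0, 1, 1, 0, 0]])
        out = tt.cluster_rules(m, cutoff_height=1e-6)
        assert out.n_clusters == 3

    def test_merge_heights_nondecreasing(self):
        rng = np.random.default_rng(6)
        m = self._membership(rng.integers(0, 2, (8, 6)).tolist())
        out = tt.cluster_rules(m, k=3)
        assert (np.diff(out.linkage_matrix[:, 2]) >= -1e-9).all()

    def test_too_few_rules_rejected(self):
        with pytest.raises(ValueError):
            tt.cluster_rules(self._membership([[1, 0, 0, 0, 0, 0]]), k=1)


class TestHubs:
    def test_most_targeted_gene_first(self):
        ranked = ranked_from([(f"m{i}", i, 1.0) for i in range(1, 5)])
        rows = [(f"m{i}", "VEGFA", np.nan) for i in range(1, 5)]
        rows += [("m1", "PTEN", np.nan), ("m2", "PTEN", np.nan)]
        db = db_from(rows)
        votes = tt.translate_votes(ranked, db)
        gene_hubs, mirna_hubs = tt.hub_report(votes, ranked, db, min_degree=2)
        assert gene_hubs.index[0] == "VEGFA"
        assert set(mirna_hubs.index) == {"m1", "m2"}  # each targets two genes
        _, all_mirnas = tt.hub_report(votes, ranked, db, min_degree=1)
        assert set(all_mirnas.index) == {"m1", "m2", "m3", "m4"}

    def test_empty_votes(self):
        ranked = ranked_from([("m1", 1, 1.0)])
        g, m = tt.hub_report(pd.DataFrame(), ranked, db_from([("m1", "G1", np.nan)]))
        assert g.empty and m.empty


class TestIO:
    def test_gmt_round_trip(self, tmp_path):
        path = tmp_path / "sets.gmt"
        path.write_text("cell_cycle\tdesc\tCDK2\tCDK4\n" "apoptosis\t-\tBCL2\n")
        sets = tt.read_gmt(path)
        assert sets == {"cell_cycle": {"CDK2", "CDK4"}, "apoptosis": {"BCL2"}}

    def test_malformed_gmt_rejected(self, tmp_path):
        path = tmp_path / "bad.gmt"
        path.write_text("only_name\tdesc\n")
        with pytest.raises(ValueError):
            tt.read_gmt(path)

    def test_targets_tsv_validation(self, tmp_path):
        path = tmp_path / "targets.tsv"
        path.write_text(
            "mirna_id\tgene_id\tprobability\tsource\n"
            "hsa-miR-1\tVEGFA\t\tvalidated\n"
            "hsa-miR-1\tPTEN\t0.7\tpredicted\n"
        )
        db = tt.read_targets_tsv(path)
        assert len(db) == 2
        assert np.isnan(db["probability"].iloc[0])

    def test_bad_probability_rejected(self, tmp_path):
        path = tmp_path / "targets.tsv"
        path.write_text("mirna_id\tgene_id\tprobability\nm1\tG1\t1.5\n")
        with pytest.raises(ValueError):
            tt.read_targets_tsv(path)
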