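import numpy as np
import pandas as pd
import pytest

from plasmirna import preprocess as pp
from plasmirna import synthetic_data as sd
from tests.conftest import make_matrix


class TestBackground:
    def test_mean_plus_two_sd(self):
        m = make_matrix(
            {"hsa-miR-1": [5], "NEG_A": [10], "NEG_B": [12], "NEG_C": [14]},
            {"NEG_A": "negative_control", "NEG_B": "negative_control",
             "NEG_C": "negative_control"},
        )
        bg = pp.estimate_background(m)
        assert bg.per_sample_threshold["S1"] == pytest.approx(16.0)

    def test_all_zero_negatives_give_zero_threshold(self):
        m = make_matrix(
            {"hsa-miR-1": [5], "NEG_A": [0], "NEG_B": [0]},
            {"NEG_A": "negative_control", "NEG_B": "negative_control"},
        )
        assert pp.estimate_background(m).per_sample_threshold["S1"] == 0.0

    def test_single_negative_control_rejected(self):
        m = make_matrix(
            {"hsa-miR-1": [5], "NEG_A": [10]}, {"NEG_A": "negative_control"}
        )
        with pytest.raises(pp.ConfigurationError):
            pp.estimate_background(m)


def _detection_matrix(n_below: int, n_samples: int = 10):
    """One probe below background in n_below of n_samples samples."""
    # negatives [10, 12, 14] per sample -> threshold 16 everywhere
    probe = [10 if j < n_below else 100 for j in range(n_samples)]
    counts = {
        "hsa-miR-x": probe,
        "NEG_A": [10] * n_samples,
        "NEG_B": [12] * n_samples,
        "NEG_C": [14] * n_samples,
    }
    classes = {k: "negative_control" for k in ("NEG_A", "NEG_B", "NEG_C")}
    return make_matrix(counts, classes)


class TestDetectionFilters:
    def test_boundary_at_least_80pct_removes(self):
        m = _detection_matrix(8)
        bg = pp.estimate_background(m)
        filtered, report = pp.filter_nondetectable(m, bg, frac=0.8)
        assert "hsa-miR-x" not in filtered.probes.index
        assert report["reason"].tolist() == ["nondetectable"]

    def test_below_boundary_retained(self):
        m = _detection_matrix(7)
        bg = pp.estimate_background(m)
        filtered, _ = pp.filter_nondetectable(m, bg, frac=0.8)
        assert "hsa-miR-x" in filtered.probes.index

    def test_excluded_probe_removed_even_when_detected(self):
        m = make_matrix(
            {"hsa-miR-720": [500, 500], "hsa-miR-1": [500, 500],
             "NEG_A": [10, 10], "NEG_B": [12, 12]},
            {"NEG_A": "negative_control", "NEG_B": "negative_control"},
        )
        bg = pp.estimate_background(m)
        filtered, report = pp.filter_nondetectable(m, bg)
        assert "hsa-miR-720" not in filtered.probes.index
        assert "excluded" in set(report["reason"])

    def test_controls_never_removed(self):
        m = _detection_matrix(10)
        bg = pp.estimate_background(m)
        filtered, _ = pp.filter_nondetectable(m, bg)
        assert set(filtered.negative_control_ids) == {"NEG_A", "NEG_B", "NEG_C"}

    def test_removed_set_monotone_in_frac(self, small_sim):
        matrix, _, _ = small_sim
        bg = pp.estimate_background(matrix)
        removed = {}
        for frac in (0.5, 0.8, 1.0):
            _, report = pp.filter_nondetectable(matrix, bg, frac=frac)
            removed[frac] = set(report.loc[report["reason"] == "nondetectable", "probe_id"])
        assert removed[1.0] <= removed[0.8] <= removed[0.5]

    def test_comparison_filter_boundaries(self):
        # 16 samples per group; probe below threshold in 3/16 both groups kept,
        # 4/16 in one group dropped
        n = 16
        counts = {
            "hsa-miR-kept": [10] * 3 + [100] * (n - 3) + [10] * 3 + [100] * (n - 3),
            "hsa-miR-dropped": [10] * 4 + [100] * (n - 4) + [100] * n,
            "hsa-miR-always": [100] * (2 * n),
            "NEG_A": [10] * (2 * n),
            "NEG_B": [12] * (2 * n),
            "NEG_C": [14] * (2 * n),
        }
        classes = {k: "negative_control" for k in ("NEG_A", "NEG_B", "NEG_C")}
        m = make_matrix(counts, classes)
        design = pd.DataFrame(
            {
                "sample_id": [f"S{i + 1}" for i in range(2 * n)],
                "group": ["GP"] * n + ["HI"] * n,
            }
        )
        bg = pp.estimate_background(m)
        kept = pp.filter_for_comparison(m, bg, design, frac=0.2)
        assert kept == {"hsa-miR-kept", "hsa-miR-always"}

    def test_comparison_filter_needs_two_groups(self, tiny_matrix):
        bg = pp.estimate_background(tiny_matrix)
        design = pd.DataFrame({"sample_id": ["S1", "S2", "S3", "S4"], "group": ["GP"] * 4})
        with pytest.raises(ValueError):
            pp.filter_for_comparison(tiny_matrix, bg, design)


class TestNormalize:
    def test_total_content_factors_and_conservation(self):
        m = make_matrix(
            {"hsa-miR-1": [60, 120], "hsa-miR-2": [40, 80],
             "NEG_A": [0, 0], "NEG_B": [0, 0]},
            {"NEG_A": "negative_control", "NEG_B": "negative_control"},
        )
        norm = pp.normalize(m, "total_content")
        assert norm.scale_factors["S1"] == pytest.approx(1.5)
        assert norm.scale_factors["S2"] == pytest.approx(0.75)
        scaled = np.exp2(norm.values.loc[m.endogenous_ids]) - 1.0
        totals = scaled.sum(axis=0)
        assert totals["S1"] == pytest.approx(totals["S2"], rel=1e-9)
        assert totals["S1"] == pytest.approx(150.0, rel=1e-9)

    def test_all_equal_matrix_is_identity(self, tiny_matrix):
        m = make_matrix(
            {"hsa-miR-1": [100, 100], "hsa-miR-2": [7, 7],
             "NEG_A": [1, 1], "NEG_B": [2, 2]},
            {"NEG_A": "negative_control", "NEG_B": "negative_control"},
        )
        for strategy in ("total_content",):
            norm = pp.normalize(m, strategy)
            assert (norm.scale_factors == 1.0).all()
            assert norm.values.loc["hsa-miR-1", "S1"] == pytest.approx(np.log2(101))

    def test_count_three_factor_one_gives_two(self):
        m = make_matrix(
            {"hsa-miR-1": [3], "NEG_A": [0], "NEG_B": [0]},
            {"NEG_A": "negative_control", "NEG_B": "negative_control"},
        )
        norm = pp.normalize(m, "total_content")
        assert norm.values.loc["hsa-miR-1", "S1"] == pytest.approx(2.0)

    def test_scale_equivariance(self, small_sim):
        """Multiplying one sample's counts by c>0 only rescales the common
        normalization target: every scaled count changes by one global factor,
        so all between-sample and between-probe contrasts are untouched."""
        matrix, _, _ = small_sim
        norm1 = pp.normalize(matrix, "total_content")
        scaled_counts = matrix.counts.copy()
        scaled_counts.iloc[:, 0] *= 3
        m2 = type(matrix)(probes=matrix.probes.copy(), counts=scaled_counts)
        norm2 = pp.normalize(m2, "total_content")
        lin1 = np.exp2(norm1.values) - 1.0
        lin2 = np.exp2(norm2.values) - 1.0
        mask = lin1 > 0
        ratio = (lin2[mask] / lin1[mask]).stack()
        np.testing.assert_allclose(ratio, ratio.iloc[0], rtol=1e-9)

    def test_zero_total_rejected(self):
        m = make_matrix(
            {"hsa-miR-1": [0, 10], "NEG_A": [0, 0], "NEG_B": [0, 0]},
            {"NEG_A": "negative_control", "NEG_B": "negative_control"},
        )
        with pytest.raises(pp.NormalizationError):
            pp.normalize(m, "total_content")


class TestSelectNormalization:
    def test_pure_library_scaling_selects_total_content(self):
        """When the only between-sample variation is a global scale factor,
        totals remove it exactly and total_content minimizes replicate CV."""
        rng = np.random.default_rng(0)
        cfg = sd.SimConfig(
            n_hi=4, n_replicates=3, n_gp=2, n_human_probes=30, n_viral_probes=5,
            n_expressed_human=25, n_expressed_viral=1,
            sigma_inter=0.0, sigma_intra=0.0, dispersion=0.01, lib_sigma=0.4,
        )
        matrix, design, _ = sd.simulate_dataset(cfg, seed=int(rng.integers(1 << 30)))
        best, scores = pp.select_normalization(matrix, design)
        assert best == "total_content"
        assert set(scores) == set(pp.STRATEGIES)

    def test_tie_breaks_to_total_content(self, hi_design):
        m = make_matrix(
            {"hsa-miR-1": [100] * 4, "hsa-miR-2": [40] * 4, "POS_A": [500] * 4,
             "NEG_A": [1] * 4, "NEG_B": [2] * 4},
            {"POS_A": "positive_control", "NEG_A": "negative_control",
             "NEG_B": "negative_control"},
        )
        best, scores = pp.select_normalization(m, hi_design)
        assert best == "total_content"
        assert len(set(np.round(list(scores.values()), 12))) == 1  # true tie

    def test_single_replicate_rejected(self, tiny_matrix, hi_design):
        solo = hi_design.drop_duplicates("subject_id")
        with pytest.raises(pp.SelectionError):
            pp.select_normalization(tiny_matrix, solo)
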