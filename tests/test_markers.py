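"""Median-of-ratios normalization and AUC-based marker selection."""

import numpy as np
import pandas as pd
import pytest

from mmflowps import markers
from mmflowps.simdata import SimConfig, simulate_cohort


class TestSizeFactors:
    def test_identical_samples_get_unit_factors(self):
        col = np.array([5, 10, 20, 40])
        counts = pd.DataFrame({"s1": col, "s2": col, "s3": col}, index=list("abcd"))
        norm = markers.size_factor_normalize(counts)
        assert np.allclose(norm.size_factors, 1.0)
        assert norm.reference_genes == list("abcd")

    def test_doubled_column_splits_geometrically(self):
        # column2 = 2 x column1: geometric means are c*sqrt(2), so the
        # ratio medians are 1/sqrt(2) and sqrt(2)
        counts = pd.DataFrame({"s1": [10, 20, 30], "s2": [20, 40, 60]},
                              index=list("abc"))
        norm = markers.size_factor_normalize(counts)
        assert norm.size_factors["s1"] == pytest.approx(1 / np.sqrt(2))
        assert norm.size_factors["s2"] == pytest.approx(np.sqrt(2))

    def test_scaling_one_sample_absorbed_up_to_global_constant(self):
        # scaling sample j by c rescales every gene's geometric mean by
        # c^(1/n), so size-factor *ratios* shift by exactly c and the
        # normalized matrix changes only by one global constant
        rng = np.random.default_rng(0)
        counts = pd.DataFrame(rng.integers(1, 500, size=(50, 6)),
                              index=[f"G{i}" for i in range(50)],
                              columns=[f"S{j}" for j in range(6)])
        norm = markers.size_factor_normalize(counts)
        scaled = counts.copy()
        scaled["S2"] = counts["S2"] * 3
        norm_scaled = markers.size_factor_normalize(scaled)
        ratio_before = norm.size_factors["S2"] / norm.size_factors["S0"]
        ratio_after = norm_scaled.size_factors["S2"] / norm_scaled.size_factors["S0"]
        assert ratio_after == pytest.approx(3 * ratio_before)
        global_factor = (
            norm_scaled.expression.to_numpy() / norm.expression.to_numpy()
        )
        assert np.allclose(global_factor, global_factor.ravel()[0])

    def test_zero_containing_genes_excluded_from_reference(self):
        counts = pd.DataFrame({"s1": [0, 10, 30], "s2": [5, 10, 30]},
                              index=list("abc"))
        norm = markers.size_factor_normalize(counts)
        assert norm.reference_genes == ["b", "c"]

    def test_all_genes_contain_zero_is_an_error(self):
        counts = pd.DataFrame({"s1": [0, 3], "s2": [5, 0]}, index=list("ab"))
        with pytest.raises(ValueError, match="pseudocount"):
            markers.size_factor_normalize(counts)


class TestGeneAuc:
    @pytest.mark.parametrize(
        "values, labels, expected",
        [
            ((1, 2, 3, 4), ("NR", "NR", "R", "R"), 1.0),  # perfect separation
            ((1, 2, 3, 4), ("NR", "R", "R", "NR"), 0.5),  # 2 of 4 concordant
            ((1, 1, 2, 2), ("NR", "R", "NR", "R"), 0.5),  # ties counted 1/2
            ((1, 2, 3, 4), ("R", "R", "NR", "NR"), 0.0),  # fully reversed
        ],
    )
    def test_hand_examples(self, values, labels, expected):
        assert markers.gene_auc(values, labels) == pytest.approx(expected)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            markers.gene_auc([1, 2], ["R", "R"])

    def test_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            n = rng.integers(4, 10)
            values = rng.integers(0, 5, size=n).astype(float)  # frequent ties
            labels = np.array(["R", "NR"] * n)[:n]
            expected = _brute_auc(values, labels == "R")
            assert markers.gene_auc(values, labels) == pytest.approx(expected)


def _brute_auc(values, pos):
    num, den = 0.0, 0
    for i in np.flatnonzero(pos):
        for j in np.flatnonzero(~pos):
            den += 1
            if values[i] > values[j]:
                num += 1
            elif values[i] == values[j]:
                num += 0.5
    return num / den


class TestRankMarkers:
    def test_planted_up_marker_ranks_high_with_direction(self):
        for seed in range(3):
            cfg = SimConfig(n_samples=40, n_genes=200, n_markers=5,
                            effect_log2fc=3.0, dispersion=0.1,
                            responder_fraction=0.5, seed=seed)
            counts, annot, truth = simulate_cohort(cfg)
            norm = markers.size_factor_normalize(counts)
            ranking = markers.rank_markers(norm, annot["binary_label"])
            for gene, direction in truth.marker_genes.items():
                row = ranking.loc[gene]
                assert row["oriented_auc"] > 0.9
                assert row["direction"] == (
                    "up_in_R" if direction == "up" else "down_in_R"
                )

    def test_constant_gene_is_uninformative(self):
        expr = pd.DataFrame(
            {"s1": [7.0, 1.0], "s2": [7.0, 2.0], "s3": [7.0, 3.0], "s4": [7.0, 4.0]},
            index=["flat", "grad"],
        )
        ranking = markers.rank_markers(expr, pd.Series(["NR", "NR", "R", "R"],
                                                       index=expr.columns))
        assert ranking.loc["flat", "raw_auc"] == pytest.approx(0.5)
        assert ranking.loc["flat", "oriented_auc"] == pytest.approx(0.5)

    def test_label_flip_symmetry(self, small_cohort):
        counts, annot, _ = small_cohort
        norm = markers.size_factor_normalize(counts)
        labels = annot["binary_label"]
        flipped = labels.map({"R": "NR", "NR": "R"})
        r1 = markers.rank_markers(norm, labels)
        r2 = markers.rank_markers(norm, flipped)
        assert np.allclose(r2["raw_auc"], 1 - r1.loc[r2.index, "raw_auc"])
        assert np.allclose(
            r2.sort_index()["oriented_auc"], r1.sort_index()["oriented_auc"]
        )

    def test_ranking_invariant_to_sample_scaling(self, small_cohort):
        counts, annot, _ = small_cohort
        scaled = counts.copy()
        scaled.iloc[:, 0] = scaled.iloc[:, 0] * 7
        r1 = markers.rank_markers(markers.size_factor_normalize(counts),
                                  annot["binary_label"])
        r2 = markers.rank_markers(markers.size_factor_normalize(scaled),
                                  annot["binary_label"])
        assert list(r1.index) == list(r2.index)


class TestLooCoreMarkers:
    def test_strong_markers_recovered_exactly(self):
        cfg = SimConfig(n_samples=40, n_genes=300, n_markers=10,
                        effect_log2fc=4.0, dispersion=0.05,
                        responder_fraction=0.5, seed=2)
        counts, annot, truth = simulate_cohort(cfg)
        norm = markers.size_factor_normalize(counts)
        core = markers.loo_core_markers(norm, annot["binary_label"], top_k=10)
        assert set(core.genes) == set(truth.marker_genes)

    def test_core_is_subset_of_every_fold_list(self, small_cohort):
        counts, annot, _ = small_cohort
        norm = markers.size_factor_normalize(counts)
        core = markers.loo_core_markers(norm, annot["binary_label"], top_k=15)
        assert len(core.fold_lists) == counts.shape[1]
        for fold in core.fold_lists.values():
            assert set(core.genes) <= set(fold)
            assert len(fold) == 15

    def test_no_signal_core_is_reduced_and_markers_at_chance(self):
        """Under the null the LOO intersection thins the top-k list but does
        not empty it: folds share n-2 samples, so sample-extreme noise genes
        recur in every fold. What must hold: the core stays well below top_k
        and the (ineffective) planted markers appear only at chance rate."""
        for seed in (0, 1):
            cfg = SimConfig(n_samples=40, n_genes=2000, n_markers=10,
                            effect_log2fc=0.0, dispersion=0.2,
                            responder_fraction=0.5, seed=seed)
            counts, annot, truth = simulate_cohort(cfg)
            norm = markers.size_factor_normalize(counts)
            core = markers.loo_core_markers(norm, annot["binary_label"], top_k=30)
            assert len(core.genes) <= 20
            assert len(set(core.genes) & set(truth.marker_genes)) <= 2

    def test_core_shrinks_as_signal_weakens(self):
        sizes = []
        for effect in (2.0, 1.0, 0.5, 0.0):
            cfg = SimConfig(n_samples=40, n_genes=400, n_markers=15,
                            effect_log2fc=effect, dispersion=0.3,
                            responder_fraction=0.5, seed=8)
            counts, annot, _ = simulate_cohort(cfg)
            norm = markers.size_factor_normalize(counts)
            core = markers.loo_core_markers(norm, annot["binary_label"], top_k=15)
            sizes.append(len(core.genes))
        assert sizes[0] > sizes[-1]
        assert sorted(sizes, reverse=True) == sizes  # monotone over the sweep

    def test_too_few_samples_per_class_rejected(self):
        expr = pd.DataFrame(np.ones((5, 4)), columns=list("wxyz"))
        with pytest.raises(ValueError, match="3 samples"):
            markers.loo_core_markers(expr, pd.Series(list("RRRN"), index=expr.columns))


class TestTargetGeneReport:
    def test_unknown_gene_listed_in_error(self, small_cohort):
        counts, annot, _ = small_cohort
        norm = markers.size_factor_normalize(counts)
        with pytest.raises(ValueError, match="NOSUCHGENE"):
            markers.target_gene_report(norm, ["NOSUCHGENE"], annot)

    def test_null_gene_auc_below_marker_threshold(self, null_cohort):
        """A gene with no response association stays under the 0.7 oriented-AUC
        biomarker bar (checked against the permutation null spread)."""
        counts, annot, _ = null_cohort
        norm = markers.size_factor_normalize(counts)
        genes = list(counts.index[:20])
        _, aucs = markers.target_gene_report(norm, genes, annot)
        assert (aucs < 0.7).mean() >= 0.9

    def test_report_rows_follow_annotation_order(self, small_cohort):
        counts, annot, _ = small_cohort
        norm = markers.size_factor_normalize(counts)
        table, _ = markers.target_gene_report(norm, [counts.index[0]], annot)
        assert list(table.index) == list(counts.columns)
        assert "timepoint" in table.columns
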