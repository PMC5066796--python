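"""FPKM, log transform, clustering and the 2^-ddCt calculator."""
from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import rand_score

from legfam import (
    SyntheticConfig,
    cut_clusters,
    ddct_fold_change,
    fpkm,
    generate_ct_table,
    generate_expression,
    generate_genomes,
    hierarchical_cluster,
    log_transform,
)
from legfam.exceptions import DesignError


def _frame(values, genes=None, samples=None):
    values = np.atleast_2d(np.asarray(values, dtype=float))
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{j}" for j in range(values.shape[1])]
    return pd.DataFrame(values, index=genes, columns=samples)


class TestFpkm:
    def test_unit_case(self):
        counts = _frame([[100.0]])
        result = fpkm(counts, pd.Series([1.0], index=["g0"]),
                      pd.Series([1_000_000.0], index=["s0"]))
        assert result.iloc[0, 0] == pytest.approx(100.0)

    def test_scale_invariance(self):
        counts = _frame([[10, 40], [5, 80]])
        lengths = pd.Series([0.5, 2.0], index=["g0", "g1"])
        totals = pd.Series([1e6, 2e6], index=["s0", "s1"])
        base = fpkm(counts, lengths, totals)
        doubled = fpkm(2 * counts, lengths, 2 * totals)
        pd.testing.assert_frame_equal(base, doubled)

    def test_zero_length_rejected(self):
        counts = _frame([[1.0]])
        with pytest.raises(ValueError):
            fpkm(counts, pd.Series([0.0], index=["g0"]),
                 pd.Series([1e6], index=["s0"]))
        with pytest.raises(ValueError):
            fpkm(counts, pd.Series([1.0], index=["g0"]),
                 pd.Series([0.0], index=["s0"]))

    def test_noise_free_generator_counts_recover_planted_abundances(self):
        fixture = generate_genomes(
            SyntheticConfig(species_count=1, genes_per_species=30, seed=3,
                            planted_tandem_pairs=0,
                            planted_segmental_pairs=0)
        )
        expr = generate_expression(fixture.truth, seed=3, dispersion=0.0)
        result = fpkm(expr.counts, expr.lengths_kb, expr.totals)
        ratio = result.values / expr.block_means.values
        assert np.allclose(ratio, 1.0)


class TestLogTransform:
    def test_zero_maps_to_zero_with_unit_offset(self):
        assert log_transform(_frame([[0.0]])).iloc[0, 0] == 0.0

    def test_ninety_nine_maps_to_two(self):
        assert log_transform(_frame([[99.0]])).iloc[0, 0] == pytest.approx(2.0)

    def test_preserves_within_gene_rank_order(self, rng):
        frame = _frame(rng.random((5, 8)) * 1000)
        logged = log_transform(frame)
        for gene in frame.index:
            assert (
                frame.loc[gene].rank() == logged.loc[gene].rank()
            ).all()

    def test_negative_values_rejected(self):
        with pytest.raises(ValueError):
            log_transform(_frame([[-1.0]]))


class TestHierarchicalClustering:
    def test_identical_rows_merge_first_at_height_zero(self):
        frame = _frame([[1, 2, 3], [1, 2, 3], [9, 9, 9]])
        result = hierarchical_cluster(frame)
        assert result.linkage[0, 2] == 0.0  # first merge at distance 0
        members = cut_clusters(result, 2)
        assert members["g0"] == members["g1"] != members["g2"]

    def test_single_gene_is_degenerate(self):
        result = hierarchical_cluster(_frame([[1, 2, 3]]))
        assert result.leaf_order == ["g0"]
        assert cut_clusters(result, 2) == {"g0": 1}

    def test_nan_rejected(self):
        frame = _frame([[1, np.nan], [2, 3]])
        with pytest.raises(ValueError):
            hierarchical_cluster(frame)

    def test_planted_two_block_structure_recovered(self):
        """Average-linkage clustering at k=2 separates the planted
        expression blocks (Rand index >= 0.95)."""
        fixture = generate_genomes(
            SyntheticConfig(species_count=1, genes_per_species=40, seed=5,
                            planted_tandem_pairs=0,
                            planted_segmental_pairs=0)
        )
        expr = generate_expression(
            fixture.truth, seed=5, dispersion=0.05, fold_separation=8.0
        )
        matrix = log_transform(fpkm(expr.counts, expr.lengths_kb, expr.totals))
        result = hierarchical_cluster(matrix, linkage="average")
        members = cut_clusters(result, 2)
        truth_blocks = [
            fixture.truth.genes[g].expression_block for g in matrix.index
        ]
        predicted = [members[g] for g in matrix.index]
        assert rand_score(truth_blocks, predicted) >= 0.95


class TestDdct:
    def _table(self, rows):
        return pd.DataFrame(
            rows, columns=["gene", "condition", "replicate", "ct_target",
                           "ct_endogenous"],
        )

    def test_zero_ddct_means_fold_one(self):
        table = self._table([
            ("g", "control", 1, 25.0, 20.0),
            ("g", "stressed", 1, 27.0, 22.0),
        ])
        result = ddct_fold_change(table)
        assert result.loc[0, "fold_change"] == pytest.approx(1.0)

    def test_minus_two_ddct_means_fourfold(self):
        table = self._table([
            ("g", "control", 1, 25.0, 20.0),
            ("g", "stressed", 1, 23.0, 20.0),
        ])
        result = ddct_fold_change(table)
        assert result.loc[0, "ddct"] == pytest.approx(-2.0)
        assert result.loc[0, "fold_change"] == pytest.approx(4.0)

    def test_replicates_averaged_on_ct_scale(self):
        table = self._table([
            ("g", "control", 1, 25.0, 20.0),
            ("g", "control", 2, 26.0, 20.0),
            ("g", "stressed", 1, 24.0, 20.0),
            ("g", "stressed", 2, 25.0, 20.0),
        ])
        result = ddct_fold_change(table)
        assert result.loc[0, "ddct"] == pytest.approx(-1.0)

    def test_missing_endogenous_control_is_an_error(self):
        table = self._table([
            ("g", "control", 1, 25.0, np.nan),
            ("g", "stressed", 1, 23.0, 20.0),
        ])
        with pytest.raises(ValueError, match="missing Ct"):
            ddct_fold_change(table)

    def test_missing_calibrator_condition_is_an_error(self):
        table = self._table([("g", "stressed", 1, 23.0, 20.0)])
        with pytest.raises(ValueError, match="calibrator"):
            ddct_fold_change(table)


@pytest.fixture(scope="module")
def truth():
    return generate_genomes(
        SyntheticConfig(species_count=1, genes_per_species=12, seed=2,
                        planted_tandem_pairs=0,
                        planted_segmental_pairs=0)
    ).truth


class TestCtGeneratorInverse:

    def test_planted_folds_recovered_exactly_at_zero_noise(self, truth):
        genes = sorted(truth.genes)[:4]
        folds = dict(zip(genes, (4.0, 1.0, 0.5, 7.25)))
        table = generate_ct_table(truth, folds, seed=1, noise_sd=0.0)
        result = ddct_fold_change(table).set_index("gene")
        for gene, fold in folds.items():
            assert result.loc[gene, "fold_change"] == pytest.approx(fold)

    def test_half_fold_gives_plus_one_ddct(self, truth):
        gene = sorted(truth.genes)[0]
        table = generate_ct_table(truth, {gene: 0.5}, seed=1)
        result = ddct_fold_change(table)
        assert result.loc[0, "ddct"] == pytest.approx(1.0)

    def test_unit_fold_gives_zero_ddct(self, truth):
        gene = sorted(truth.genes)[0]
        table = generate_ct_table(truth, {gene: 1.0}, seed=1)
        assert ddct_fold_change(table).loc[0, "ddct"] == pytest.approx(0.0)

    def test_invalid_folds_rejected(self, truth):
        gene = sorted(truth.genes)[0]
        with pytest.raises(ValueError):
            generate_ct_table(truth, {gene: 0.0})
        with pytest.raises(ValueError):
            generate_ct_table(truth, {"no_such_gene": 2.0})


class TestExpressionGenerator:
    def test_zero_replicates_is_a_design_error(self):
        fixture = generate_genomes(
            SyntheticConfig(species_count=1, genes_per_species=10, seed=1,
                            planted_tandem_pairs=0,
                            planted_segmental_pairs=0)
        )
        from legfam import ExperimentDesign

        with pytest.raises(DesignError):
            generate_expression(
                fixture.truth, design=ExperimentDesign(replicates=0)
            )

    def test_noise_free_flat_limit_is_proportional_to_length_and_depth(self):
        """With equal means and zero dispersion, counts reduce to
        length_kb x library_size scaling exactly."""
        fixture = generate_genomes(
            SyntheticConfig(species_count=1, genes_per_species=10, seed=1,
                            planted_tandem_pairs=0,
                            planted_segmental_pairs=0)
        )
        expr = generate_expression(
            fixture.truth, seed=4, dispersion=0.0, fold_separation=1.0,
            base_sigma=0.0,
        )
        expected = np.outer(expr.lengths_kb.values, expr.totals.values / 1e6)
        ratio = expr.counts.values / expected
        assert np.allclose(ratio, ratio[0, 0])

    def test_deterministic_per_seed(self):
        fixture = generate_genomes(
            SyntheticConfig(species_count=1, genes_per_species=10, seed=1,
                            planted_tandem_pairs=0,
                            planted_segmental_pairs=0)
        )
        a = generate_expression(fixture.truth, seed=11)
        b = generate_expression(fixture.truth, seed=11)
        pd.testing.assert_frame_equal(a.counts, b.counts)
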