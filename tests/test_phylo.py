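"""Neighbour joining, p-distances, bootstrap and clade assignment."""
from __future__ import annotations

import numpy as np
import pytest
from skbio import DistanceMatrix
from skbio.tree import nj as skbio_nj

from legfam.phylo import (
    annotate_supports,
    assign_groups,
    bootstrap_support,
    nj_tree,
    pdistance,
    tree_splits,
)


class TestPDistance:
    def test_identical_sequences_have_zero_distance(self):
        dm = pdistance({"a": "AAAA", "b": "AAAA", "c": "AAAA"})
        assert dm["a", "b"] == 0.0

    def test_single_mismatch_over_four_sites(self):
        dm = pdistance({"a": "AAAA", "b": "AAAT", "c": "TTTT"})
        assert dm["a", "b"] == pytest.approx(0.25)

    def test_pairwise_deletion_excludes_gap_columns(self):
        dm = pdistance({"a": "AA-A", "b": "AATA", "c": "AAAA"})
        assert dm["a", "b"] == 0.0  # 3 compared sites, 0 mismatches

    def test_pair_without_comparable_sites_is_an_error(self):
        with pytest.raises(ValueError, match="a.*b|b.*a"):
            pdistance({"a": "AA--", "b": "--TT", "c": "AATT"})

    def test_matrix_is_symmetric_with_zero_diagonal(self, rng):
        seqs = {
            f"t{i}": "".join(rng.choice(list("ACDEFG"), 30)) for i in range(6)
        }
        dm = pdistance(seqs)
        data = np.asarray(dm.data)
        assert np.allclose(data, data.T)
        assert np.all(np.diag(data) == 0)
        assert data.min() >= 0 and data.max() <= 1


def _additive_distances(tree_lengths):
    """Pairwise path lengths of the 4-taxon tree ((A,B),(C,D)) with the
    given branch lengths (a, b, c, d, internal)."""
    a, b, c, d, internal = tree_lengths
    return {
        ("A", "B"): a + b,
        ("A", "C"): a + internal + c,
        ("A", "D"): a + internal + d,
        ("B", "C"): b + internal + c,
        ("B", "D"): b + internal + d,
        ("C", "D"): c + d,
    }


class TestNeighbourJoining:
    def test_additive_four_taxon_matrix_recovers_tree_exactly(self):
        lengths = (2.0, 3.0, 4.0, 5.0, 1.0)
        pairs = _additive_distances(lengths)
        ids = ["A", "B", "C", "D"]
        data = np.zeros((4, 4))
        for (x, y), value in pairs.items():
            i, j = ids.index(x), ids.index(y)
            data[i, j] = data[j, i] = value
        tree = nj_tree(DistanceMatrix(data, ids=ids))
        # topology: AB|CD is the only internal split
        assert set(tree_splits(tree)) == {frozenset({"C", "D"})}
        # branch lengths are exact: every leaf-to-leaf path matches
        for (x, y), value in pairs.items():
            assert tree.find(x).distance(tree.find(y)) == pytest.approx(
                value, abs=1e-9
            )

    def test_three_taxa_closed_form(self):
        data = [[0, 3, 4], [3, 0, 5], [4, 5, 0]]
        tree = nj_tree(DistanceMatrix(np.array(data, float), ids=list("ABC")))
        lengths = {leaf.name: leaf.length for leaf in tree.tips()}
        assert lengths["A"] == pytest.approx((3 + 4 - 5) / 2)
        assert lengths["B"] == pytest.approx((3 + 5 - 4) / 2)
        assert lengths["C"] == pytest.approx((4 + 5 - 3) / 2)

    def test_taxon_permutation_leaves_topology_unchanged(self, rng):
        lengths = (1.0, 2.5, 0.5, 3.0, 2.0)
        ids = ["A", "B", "C", "D"]
        pairs = _additive_distances(lengths)
        data = np.zeros((4, 4))
        for (x, y), value in pairs.items():
            i, j = ids.index(x), ids.index(y)
            data[i, j] = data[j, i] = value
        reference_splits = set(tree_splits(nj_tree(
            DistanceMatrix(data, ids=ids)
        )))
        for _ in range(5):
            perm = rng.permutation(4)
            permuted = DistanceMatrix(
                data[np.ix_(perm, perm)], ids=[ids[i] for i in perm]
            )
            assert set(tree_splits(nj_tree(permuted))) == reference_splits

    def test_matches_independent_nj_on_random_distances(self, rng):
        """Topology agrees with scikit-bio's neighbour joining on a noisy
        (non-additive) distance matrix."""
        n = 8
        raw = rng.random((n, n))
        data = (raw + raw.T) / 2
        np.fill_diagonal(data, 0)
        ids = [f"t{i}" for i in range(n)]
        dm = DistanceMatrix(data, ids=ids)
        ours = set(tree_splits(nj_tree(dm)))
        theirs = set(tree_splits(skbio_nj(dm)))
        assert ours == theirs

    def test_branch_lengths_never_negative(self, rng):
        for _ in range(5):
            n = 7
            raw = rng.random((n, n)) * 0.2
            data = (raw + raw.T) / 2
            np.fill_diagonal(data, 0)
            tree = nj_tree(
                DistanceMatrix(data, ids=[f"t{i}" for i in range(n)])
            )
            for node in tree.traverse(include_self=False):
                assert node.length >= 0

    def test_fewer_than_three_taxa_rejected(self):
        with pytest.raises(ValueError):
            nj_tree(DistanceMatrix(np.zeros((2, 2)), ids=["a", "b"]))


def _two_clade_alignment(rng, n_per_clade=4, length=60, divergence=12):
    """Two well-separated clades of near-identical sequences."""
    base1 = rng.choice(list("ACDEFGHIKL"), length)
    base2 = base1.copy()
    sites = rng.choice(length, size=divergence, replace=False)
    for s in sites:
        base2[s] = "W" if base2[s] != "W" else "Y"
    rows = {}
    for k in range(n_per_clade):
        for name, base in (("x", base1), ("y", base2)):
            seq = base.copy()
            pos = rng.integers(length)
            seq[pos] = "M"
            rows[f"{name}{k}"] = "".join(seq)
    return rows


class TestBootstrap:
    def test_uniform_signal_gives_full_support(self):
        alignment = {
            "a": "AAAA", "b": "AAAA", "c": "TTTT", "d": "TTTT",
        }
        tree, supports = bootstrap_support(alignment, replicates=20, seed=1)
        split = frozenset({"c", "d"})
        assert supports[split] == 100.0

    def test_zero_replicates_rejected(self):
        with pytest.raises(ValueError):
            bootstrap_support({"a": "AA", "b": "AA", "c": "AA"},
                              replicates=0, seed=1)

    def test_well_separated_clades_highly_supported(self, rng):
        """The split between two planted clades reaches >=95% support on
        average over 10 seeds at 100 replicates."""
        values = []
        for seed in range(10):
            alignment = _two_clade_alignment(rng)
            tree, supports = bootstrap_support(
                alignment, replicates=100, seed=seed
            )
            split = frozenset(n for n in alignment if n.startswith("y"))
            values.append(supports.get(split, 0.0))
        assert np.mean(values) >= 95.0

    def test_supports_lie_in_percent_range(self, rng):
        alignment = {
            f"t{i}": "".join(rng.choice(list("ACDE"), 40)) for i in range(6)
        }
        _, supports = bootstrap_support(alignment, replicates=50, seed=3)
        assert all(0.0 <= v <= 100.0 for v in supports.values())

    def test_deterministic_per_seed(self, rng):
        alignment = _two_clade_alignment(rng)
        r1 = bootstrap_support(alignment, replicates=50, seed=7)[1]
        r2 = bootstrap_support(alignment, replicates=50, seed=7)[1]
        assert r1 == r2


class TestAssignGroups:
    def _tree_with_refs(self, rng):
        alignment = _two_clade_alignment(rng)
        renamed = {}
        for name, seq in alignment.items():
            if name == "x0":
                renamed["REF_A4"] = seq
            elif name == "y0":
                renamed["REF_B1"] = seq
            else:
                renamed[name] = seq
        return renamed

    def test_query_sister_to_reference_takes_its_label(self, rng):
        alignment = self._tree_with_refs(rng)
        tree, supports = bootstrap_support(alignment, replicates=50, seed=2)
        groups = assign_groups(
            tree, {"REF_A4": "A4", "REF_B1": "B1"}, supports
        )
        for query, label in groups.items():
            expected = "A4" if query.startswith("x") else "B1"
            assert label == expected, query

    def test_zero_support_edges_do_not_assign(self, rng):
        alignment = self._tree_with_refs(rng)
        tree, supports = bootstrap_support(alignment, replicates=50, seed=2)
        zeroed = {split: 0.0 for split in supports}
        groups = assign_groups(
            tree, {"REF_A4": "A4", "REF_B1": "B1"}, zeroed
        )
        assert all(label is None for label in groups.values())

    def test_missing_reference_taxon_is_an_error(self, rng):
        alignment = self._tree_with_refs(rng)
        tree = nj_tree(pdistance(alignment))
        with pytest.raises(ValueError, match="REF_MISSING"):
            assign_groups(tree, {"REF_MISSING": "A1"})

    def test_annotate_supports_writes_internal_labels(self, rng):
        alignment = self._tree_with_refs(rng)
        tree, supports = bootstrap_support(alignment, replicates=20, seed=5)
        annotate_supports(tree, supports)
        labels = [
            node.name for node in tree.non_tips(include_self=False)
            if node.name is not None
        ]
        assert labels, "expected at least one annotated internal node"
        assert all(0 <= float(v) <= 100 for v in labels)
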