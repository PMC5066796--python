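"""Neighbour-joining phylogenetics on domain alignments.

Distances are p-distances with pairwise deletion (sites where either
sequence of a pair has a gap are excluded for that pair only).  Trees are
built with the Saitou-Nei neighbour-joining algorithm; negative branch
lengths are clamped to zero with the deficit transferred to the sister
branch so path lengths between the joined pair are preserved.  Bootstrap
support resamples alignment columns with replacement and counts how often
each original internal split reappears.

Subgroup assignment is clade-based: a query leaf takes the label of the
reference-defined clade with which it forms a monophyletic group at
bootstrap support >= 50% (the smallest qualifying clade wins).

Trees are scikit-bio ``TreeNode`` objects, exportable as Newick with
bootstrap percentages as internal node labels.
"""
from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
from skbio import DistanceMatrix, TreeNode

from .records import AMINO_ACIDS

GAP_CHARS = set("-.")
SUPPORT_THRESHOLD = 50.0


def _matrix_from_alignment(
    alignment: Mapping[str, str] | Sequence[tuple[str, str]],
) -> tuple[list[str], np.ndarray, np.ndarray]:
    items = (
        list(alignment.items())
        if isinstance(alignment, Mapping)
        else list(alignment)
    )
    names = [name for name, _ in items]
    seqs = [seq.upper() for _, seq in items]
    if len(names) != len(set(names)):
        raise ValueError("duplicate taxon names in alignment")
    if not seqs:
        raise ValueError("empty alignment")
    width = len(seqs[0])
    if any(len(s) != width for s in seqs):
        raise ValueError("alignment rows have inconsistent lengths")
    codes = np.zeros((len(seqs), width), dtype=np.int8)
    lookup = {aa: i for i, aa in enumerate(AMINO_ACIDS)}
    gap_code = -1
    for i, seq in enumerate(seqs):
        codes[i] = [
            gap_code if c in GAP_CHARS else lookup.get(c, len(AMINO_ACIDS))
            for c in seq
        ]
    nongap = codes != gap_code
    return names, codes, nongap


def _pdistance_arrays(
    codes: np.ndarray, nongap: np.ndarray
) -> np.ndarray:
    """Pairwise p-distance matrix under pairwise deletion (vectorised)."""
    valid = nongap.astype(np.float64)
    comparable = valid @ valid.T
    matches = np.zeros_like(comparable)
    for code in np.unique(codes[nongap]):
        mask = ((codes == code) & nongap).astype(np.float64)
        matches += mask @ mask.T
    with np.errstate(invalid="ignore", divide="ignore"):
        dist = np.where(comparable > 0, 1.0 - matches / comparable, np.nan)
    np.fill_diagonal(dist, 0.0)
    return dist


def pdistance(
    alignment: Mapping[str, str] | Sequence[tuple[str, str]],
) -> DistanceMatrix:
    """p-distance matrix (mismatches / compared sites) with pairwise
    deletion.  A pair with zero comparable sites is an error."""
    names, codes, nongap = _matrix_from_alignment(alignment)
    if len(names) < 3:
        raise ValueError("pdistance requires at least 3 sequences")
    dist = _pdistance_arrays(codes, nongap)
    if np.isnan(dist).any():
        bad = np.argwhere(np.isnan(dist))
        i, j = bad[0]
        raise ValueError(
            f"no comparable sites between {names[i]!r} and {names[j]!r}"
        )
    return DistanceMatrix(dist, ids=names)


def nj_tree(dm: DistanceMatrix) -> TreeNode:
    """Saitou-Nei neighbour joining.

    Deterministic: ties in the Q-criterion are broken first by the smaller
    pairwise distance (so identical taxa agglomerate before being drawn
    towards other clusters) and then by the (sorted) names of the smallest
    leaf in each candidate cluster.  Returns an unrooted tree represented
    with a trifurcating root.
    """
    names = list(dm.ids)
    if len(names) < 3:
        raise ValueError("neighbour joining requires at least 3 taxa")
    D = np.array(dm.data, dtype=np.float64)
    nodes: list[TreeNode] = [TreeNode(name=n) for n in names]
    reps = list(names)  # smallest leaf name per active cluster

    while len(nodes) > 3:
        n = len(nodes)
        r = D.sum(axis=1)
        Q = (n - 2) * D - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        qmin = Q.min()
        candidates = np.argwhere(Q == qmin)
        i, j = min(
            (D[a, b], tuple(sorted((reps[a], reps[b]))),
             (min(a, b), max(a, b)))
            for a, b in candidates
        )[2]
        limb_i = 0.5 * D[i, j] + (r[i] - r[j]) / (2.0 * (n - 2))
        limb_j = D[i, j] - limb_i
        limb_i, limb_j = _clamp_pair(limb_i, limb_j)
        parent = TreeNode(children=[nodes[i], nodes[j]])
        nodes[i].length = limb_i
        nodes[j].length = limb_j
        d_new = 0.5 * (D[i, :] + D[j, :] - D[i, j])
        keep = [k for k in range(n) if k not in (i, j)]
        D = np.vstack([D[np.ix_(keep, keep)], d_new[keep]])
        D = np.hstack([D, np.append(d_new[keep], 0.0)[:, None]])
        nodes = [nodes[k] for k in keep] + [parent]
        reps = [reps[k] for k in keep] + [min(reps[i], reps[j])]

    # final star join of the three remaining clusters
    d01, d02, d12 = D[0, 1], D[0, 2], D[1, 2]
    lengths = [
        0.5 * (d01 + d02 - d12),
        0.5 * (d01 + d12 - d02),
        0.5 * (d02 + d12 - d01),
    ]
    for node, length in zip(nodes, lengths):
        node.length = max(length, 0.0)
    return TreeNode(children=nodes)


def _clamp_pair(limb_a: float, limb_b: float) -> tuple[float, float]:
    if limb_a < 0:
        limb_b += limb_a
        limb_a = 0.0
    if limb_b < 0:
        limb_a += limb_b
        limb_b = 0.0
    return max(limb_a, 0.0), max(limb_b, 0.0)


def tree_splits(tree: TreeNode) -> dict[frozenset, TreeNode]:
    """Non-trivial splits of an unrooted tree, canonicalised as the side
    not containing the alphabetically first taxon."""
    leaves = frozenset(leaf.name for leaf in tree.tips())
    anchor = min(leaves)
    splits: dict[frozenset, TreeNode] = {}
    for node in tree.non_tips(include_self=False):
        side = frozenset(leaf.name for leaf in node.tips())
        if anchor in side:
            side = leaves - side
        if 2 <= len(side) <= len(leaves) - 2:
            splits[side] = node
    return splits


def bootstrap_support(
    alignment: Mapping[str, str] | Sequence[tuple[str, str]],
    replicates: int,
    seed: int,
) -> tuple[TreeNode, dict[frozenset, float]]:
    """NJ tree of the alignment plus per-split bootstrap support (%).

    Columns are resampled with replacement ``replicates`` times;
    support of an original internal split is the percentage of replicate
    trees containing it.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    names, codes, nongap = _matrix_from_alignment(alignment)
    tree = nj_tree(pdistance(alignment))
    target_splits = list(tree_splits(tree))
    hits = {split: 0 for split in target_splits}
    rng = np.random.default_rng(seed)
    n_cols = codes.shape[1]
    for _ in range(replicates):
        idx = rng.integers(0, n_cols, size=n_cols)
        sub_codes, sub_nongap = codes[:, idx], nongap[:, idx]
        dist = _pdistance_arrays(sub_codes, sub_nongap)
        if np.isnan(dist).any():
            continue  # a pair lost all comparable sites in this replicate
        rep_tree = nj_tree(DistanceMatrix(dist, ids=names))
        rep_splits = tree_splits(rep_tree)
        for split in target_splits:
            if split in rep_splits:
                hits[split] += 1
    supports = {
        split: 100.0 * count / replicates for split, count in hits.items()
    }
    return tree, supports


def annotate_supports(
    tree: TreeNode, supports: dict[frozenset, float]
) -> TreeNode:
    """Write support percentages onto internal node names (for Newick
    export, where they appear as internal labels)."""
    splits = tree_splits(tree)
    for split, node in splits.items():
        if split in supports:
            node.name = f"{supports[split]:.0f}"
    return tree


def assign_groups(
    tree: TreeNode,
    references: Mapping[str, str],
    supports: dict[frozenset, float] | None = None,
    min_support: float = SUPPORT_THRESHOLD,
) -> dict[str, str | None]:
    """Clade-based subgroup assignment.

    ``references`` maps reference leaf names to subgroup labels.  Each
    query leaf receives the label of the clade (either side of an internal
    edge, at support >= ``min_support``) that contains the query and
    references of exactly one subgroup; among qualifying clades the one
    whose nearest in-clade reference is closest to the query by path
    length wins, then the smallest.  The distance preference matters when
    near-identical taxa make the local branching order arbitrary: the
    query then still follows its closest reference rather than an
    accidental resolution.  Queries with no qualifying clade get None.
    When ``supports`` is None every edge qualifies.
    """
    leaves = frozenset(leaf.name for leaf in tree.tips())
    missing = set(references) - leaves
    if missing:
        raise ValueError(f"reference taxa absent from tree: {sorted(missing)}")
    queries = sorted(leaves - set(references))
    tips = {leaf.name: leaf for leaf in tree.tips()}

    sides: list[frozenset] = []
    for split in tree_splits(tree):
        if supports is not None and supports.get(split, 0.0) < min_support:
            continue
        sides.append(split)
        sides.append(leaves - split)

    assignments: dict[str, str | None] = {}
    for query in queries:
        ref_distance = {
            ref: tips[query].distance(tips[ref]) for ref in references
        }
        best: tuple[float, int, tuple, str] | None = None
        for side in sides:
            if query not in side:
                continue
            in_side = [r for r in side if r in references]
            labels = {references[r] for r in in_side}
            if len(labels) != 1:
                continue
            nearest = min(ref_distance[r] for r in in_side)
            key = (nearest, len(side), tuple(sorted(side)), labels.pop())
            if best is None or key < best:
                best = key
        assignments[query] = best[3] if best else None
    return assignments
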