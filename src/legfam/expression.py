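"""Expression profiling: FPKM, log transform, clustering and 2^-ddCt.

FPKM is fragments per kilobase of transcript per million mapped fragments.
Heatmap preparation log10-transforms FPKM with a +1 offset (zeros map to
zero) and orders genes by average-linkage hierarchical clustering.  The
qRT-PCR calculator implements the 2^-ddCt relative-quantification method:
replicate Ct values are averaged on the Ct scale, normalised to the
endogenous control, and referenced to the calibrator sample.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist


def fpkm(
    counts: pd.DataFrame,
    lengths_kb: pd.Series,
    totals: pd.Series,
) -> pd.DataFrame:
    """FPKM[g, s] = counts[g, s] / (length_kb[g] * totals[s] / 1e6).

    ``counts`` is genes x samples; ``lengths_kb`` transcript lengths in kb
    per gene; ``totals`` mapped fragments per sample.
    """
    lengths_kb = lengths_kb.reindex(counts.index)
    totals = totals.reindex(counts.columns)
    if lengths_kb.isna().any() or (lengths_kb <= 0).any():
        raise ValueError("every gene needs a positive transcript length")
    if totals.isna().any() or (totals <= 0).any():
        raise ValueError("every sample needs a positive mapped-fragment total")
    return counts.div(lengths_kb, axis=0).div(totals / 1e6, axis=1)


def log_transform(matrix: pd.DataFrame, offset: float = 1.0) -> pd.DataFrame:
    """log10(value + offset); the +1 default maps FPKM 0 to 0."""
    if (matrix.values < 0).any():
        raise ValueError("expression values must be non-negative")
    if offset <= 0 and (matrix.values <= 0).any():
        raise ValueError("offset must be positive when zeros are present")
    return np.log10(matrix + offset)


@dataclass
class ClusterResult:
    genes: list[str]               # gene ids in input row order
    linkage: np.ndarray            # scipy linkage matrix
    leaf_order: list[str]          # gene ids in dendrogram order
    ordered: pd.DataFrame          # input rows reordered for heatmap


def hierarchical_cluster(
    matrix: pd.DataFrame,
    linkage: str = "average",
    metric: str = "euclidean",
) -> ClusterResult:
    """Agglomerative clustering of genes (rows) for heatmap ordering.

    Metric is euclidean or correlation; deterministic (scipy breaks ties
    on the lowest pair index).  Single-gene input yields the degenerate
    one-leaf result.
    """
    if matrix.isna().any().any():
        raise ValueError("expression matrix contains NaN")
    genes = matrix.index.tolist()
    if len(genes) < 2:
        return ClusterResult(
            genes=genes,
            linkage=np.empty((0, 4)),
            leaf_order=genes,
            ordered=matrix.copy(),
        )
    distances = pdist(matrix.values, metric=metric)
    Z = hierarchy.linkage(distances, method=linkage)
    order = hierarchy.leaves_list(Z)
    leaf_order = [genes[i] for i in order]
    return ClusterResult(
        genes=genes, linkage=Z, leaf_order=leaf_order,
        ordered=matrix.loc[leaf_order],
    )


def cut_clusters(result: ClusterResult, k: int) -> dict[str, int]:
    """Flat cluster membership at k clusters, keyed by gene id."""
    if result.linkage.size == 0:
        return {g: 1 for g in result.genes}
    labels = hierarchy.fcluster(result.linkage, k, criterion="maxclust")
    return dict(zip(result.genes, (int(x) for x in labels)))


def ddct_fold_change(
    ct: pd.DataFrame,
    calibrator: str = "control",
) -> pd.DataFrame:
    """Per-gene fold change by the 2^-ddCt method.

    ``ct`` needs columns gene, condition, ct_target, ct_endogenous (and
    optionally replicate).  dCt = Ct_target - Ct_endogenous, averaged over
    replicates per (gene, condition); ddCt = dCt_condition -
    dCt_calibrator; fold = 2^-ddCt.  Returns one row per (gene,
    non-calibrator condition) with ddct and fold_change columns.
    """
    required = {"gene", "condition", "ct_target", "ct_endogenous"}
    missing = required - set(ct.columns)
    if missing:
        raise ValueError(f"Ct table lacks columns: {sorted(missing)}")
    if ct[["ct_target", "ct_endogenous"]].isna().any().any():
        bad = ct[ct[["ct_target", "ct_endogenous"]].isna().any(axis=1)]
        raise ValueError(
            "missing Ct values for sample(s): "
            + ", ".join(map(str, bad.index.tolist()[:5]))
        )
    work = ct.copy()
    work["dct"] = work["ct_target"] - work["ct_endogenous"]
    mean_dct = (
        work.groupby(["gene", "condition"])["dct"].mean().unstack("condition")
    )
    if calibrator not in mean_dct.columns:
        raise ValueError(f"no calibrator condition {calibrator!r} in Ct table")
    rows = []
    for condition in mean_dct.columns:
        if condition == calibrator:
            continue
        ddct = mean_dct[condition] - mean_dct[calibrator]
        for gene, value in ddct.dropna().items():
            rows.append(
                {
                    "gene": gene,
                    "condition": condition,
                    "ddct": value,
                    "fold_change": 2.0 ** (-value),
                }
            )
    return pd.DataFrame(rows, columns=["gene", "condition", "ddct",
                                       "fold_change"])
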