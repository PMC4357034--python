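"""Expression profiling of HTR genes across tissues and stages.

Mirrors the classic Cluster 3.0 / TreeView workflow: drop genes below the
detection floor, log2-transform, median-center per gene, hierarchically
cluster with 1 - Pearson correlation and average linkage, and emit an
ordered matrix. A simple archetype caller distinguishes constitutive
profiles from the replication-coupled pattern (high in dividing tissues —
roots, stem, seed, embryo — low in differentiated ones) and from
heterogeneous profiles.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .genome_io import ExpressionMatrix

ARCHETYPES = ("constitutive", "dividing_high", "heterogeneous")


@dataclass
class ProcessedMatrix:
    """Preprocessed expression data: log2(x+1), median-centered per gene.

    Values may be negative after centering, so this is deliberately not an
    ExpressionMatrix (whose contract is linear-scale, non-negative input).
    ``log2_values`` keeps the uncentered log2 scale for archetype calling.
    """

    gene_ids: list[str]
    tissue_labels: list[str]
    values: np.ndarray
    log2_values: np.ndarray
    excluded: list[str] = field(default_factory=list)


@dataclass
class ClusterResult:
    """Average-linkage merge tree over detected genes.

    ``merges`` is a scipy linkage matrix (n-1 joins with non-decreasing
    heights); ``leaf_order`` is the dendrogram's left-to-right permutation.
    """

    gene_ids: list[str]
    merges: np.ndarray
    leaf_order: list[int]
    excluded: list[str]

    def cut(self, k: int) -> dict[str, int]:
        labels = hierarchy.fcluster(self.merges, t=k, criterion="maxclust")
        return {g: int(l) for g, l in zip(self.gene_ids, labels)}


def preprocess(matrix: ExpressionMatrix, detection_floor: float = 1.0) -> ProcessedMatrix:
    """Filter undetected genes and transform to centered log2 scale.

    Genes whose values all fall below ``detection_floor`` are flagged
    not-detected and removed (candidate pseudogenes are reported, never
    asserted). Remaining values become log2(x+1), then per-gene
    median-centered.
    """
    values = np.asarray(matrix.values, dtype=float)
    detected = (values >= detection_floor).any(axis=1)
    excluded = [g for g, keep in zip(matrix.gene_ids, detected) if not keep]
    if not detected.any():
        raise ValueError("no genes above the detection floor")
    kept_ids = [g for g, keep in zip(matrix.gene_ids, detected) if keep]
    log2 = np.log2(values[detected] + 1.0)
    centered = log2 - np.median(log2, axis=1, keepdims=True)
    return ProcessedMatrix(kept_ids, list(matrix.tissue_labels), centered, log2, excluded)


def hierarchical_cluster(processed: ProcessedMatrix) -> ClusterResult:
    """Average-linkage clustering on 1 - Pearson correlation distances."""
    vals = processed.values
    if vals.shape[0] < 2:
        raise ValueError("need >= 2 genes to cluster")
    sd = vals.std(axis=1)
    for gene, s in zip(processed.gene_ids, sd):
        if s == 0:
            raise ValueError(f"gene {gene!r} has zero variance: correlation undefined")
    corr = np.corrcoef(vals)
    dist = 1.0 - corr
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, None)
    Z = hierarchy.linkage(squareform(dist, checks=False), method="average")
    order = hierarchy.leaves_list(Z).tolist()
    return ClusterResult(list(processed.gene_ids), Z, order, list(processed.excluded))


def call_profile_archetype(
    values: np.ndarray,
    tissue_labels: list[str],
    tissue_groups: dict[str, str],
    cv_max: float = 0.25,
    delta: float = 1.0,
) -> str:
    """Call a gene's profile archetype from its linear-scale row.

    ``tissue_groups`` maps every tissue to 'dividing' or 'differentiated'.
    Constitutive: coefficient of variation (linear scale) below ``cv_max``.
    Dividing-high: mean log2 contrast dividing - differentiated above
    ``delta``. Otherwise heterogeneous.
    """
    values = np.asarray(values, dtype=float)
    for t in tissue_labels:
        if t not in tissue_groups:
            raise ValueError(f"tissue {t!r} not assigned to a group")
        if tissue_groups[t] not in ("dividing", "differentiated"):
            raise ValueError(f"tissue {t!r}: unknown group {tissue_groups[t]!r}")
    mean = values.mean()
    if mean > 0 and values.std() / mean < cv_max:
        return "constitutive"
    log2 = np.log2(values + 1.0)
    div = [i for i, t in enumerate(tissue_labels) if tissue_groups[t] == "dividing"]
    dif = [i for i, t in enumerate(tissue_labels) if tissue_groups[t] == "differentiated"]
    if not div or not dif:
        raise ValueError("tissue_groups must contain both group kinds")
    if log2[div].mean() - log2[dif].mean() > delta:
        return "dividing_high"
    return "heterogeneous"


def write_clustered_tsv(processed: ProcessedMatrix, result: ClusterResult, path: str | Path) -> None:
    """Ordered (CDT-like) matrix: rows follow the dendrogram leaf order."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("gene_id\t" + "\t".join(processed.tissue_labels) + "\n")
        for idx in result.leaf_order:
            row = "\t".join(f"{v:.4f}" for v in processed.values[idx])
            fh.write(f"{processed.gene_ids[idx]}\t{row}\n")
        for g in result.excluded:
            fh.write(f"{g}\tNOT_DETECTED" + "\t" * (len(processed.tissue_labels) - 1) + "\n")


def write_merge_tree_tsv(result: ClusterResult, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("join\tleft\tright\theight\tsize\n")
        for k, (a, b, h, size) in enumerate(result.merges):
            fh.write(f"{k}\t{int(a)}\t{int(b)}\t{h:.6f}\t{int(size)}\n")
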