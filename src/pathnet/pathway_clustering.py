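"""Cluster enriched pathways by gene-overlap profile; pick representatives.

The overlap index of two pathways is OI_{i,j} = |G_i ∩ G_j| / min(|G_i|,
|G_j|) (1 for nested sets, 0 for disjoint).  Row i of the OI matrix is the
overlap *profile* of pathway i; profiles are compared by Pearson
correlation R and converted to pairwise distances PD = 1 − R.  Average-
linkage hierarchical clustering of the PD matrix is cut at a fixed height
(default 0.55) and the pathway with the smallest final p-value in each
cluster is flagged as that cluster's representative.

The PD matrix need not be metric (PD > 1 whenever profiles anticorrelate);
average linkage tolerates this.  The agglomeration is written out by hand
(rather than delegated) because a fixed smallest-index tie-break between
equidistant pairs is part of the contract; it is cross-checked against
scipy's average linkage on tie-free inputs in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class ClusterAssignment:
    """Flat clustering of pathways with one representative per cluster."""

    labels: dict[str, int]                  # pathway_id -> cluster label
    representatives: set[str] = field(default_factory=set)
    cut_height: float = 0.55
    merge_heights: list[float] = field(default_factory=list)

    @property
    def n_clusters(self) -> int:
        return len(set(self.labels.values()))

    def members(self, label: int) -> list[str]:
        return sorted(p for p, c in self.labels.items() if c == label)


def overlap_index_matrix(gene_sets: list[frozenset]) -> np.ndarray:
    """OI_{i,j} = |G_i ∩ G_j| / min(|G_i|, |G_j|) by exact set arithmetic."""
    if len(gene_sets) < 2:
        raise ValueError("need >=2 pathways to build an overlap matrix")
    if any(not g for g in gene_sets):
        raise ValueError("every pathway gene set must be non-empty")
    n = len(gene_sets)
    oi = np.ones((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            v = len(gene_sets[i] & gene_sets[j]) / min(len(gene_sets[i]), len(gene_sets[j]))
            oi[i, j] = oi[j, i] = v
    return oi


def profile_distances(oi: np.ndarray, include_diagonal: bool = True) -> np.ndarray:
    """PD = 1 − Pearson R between overlap profiles (full OI rows).

    By default the profile is the complete row including the self-entry.
    Zero-variance profiles have no defined correlation; by convention R = 1
    (PD = 0) when the two rows are identical and R = 0 (PD = 1) otherwise.
    """
    n = oi.shape[0]
    pd_mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            if include_diagonal:
                a, b = oi[i], oi[j]
            else:
                mask = np.ones(n, dtype=bool)
                mask[[i, j]] = False
                a, b = oi[i][mask], oi[j][mask]
            if a.std() == 0.0 or b.std() == 0.0:
                r = 1.0 if np.array_equal(a, b) else 0.0
            else:
                r = float(np.corrcoef(a, b)[0, 1])
            pd_mat[i, j] = pd_mat[j, i] = 1.0 - r
    return pd_mat


def average_linkage_labels(
    pd_mat: np.ndarray, cut: float
) -> tuple[np.ndarray, list[float]]:
    """Agglomerative average linkage; flat clusters at height *cut*.

    Merging stops once the closest pair is farther apart than *cut* (so the
    flat clusters are exactly the dendrogram cut at that height).  Among
    equidistant pairs the one with the smallest (i, j) cluster indices is
    merged first, making the result deterministic.  Returns integer labels
    numbered by first pathway occurrence and the list of merge heights.
    """
    n = pd_mat.shape[0]
    clusters: dict[int, list[int]] = {i: [i] for i in range(n)}
    dist = {
        (i, j): float(pd_mat[i, j])
        for i in range(n) for j in range(i + 1, n)
    }
    heights: list[float] = []
    next_id = n
    while len(clusters) > 1:
        (ci, cj), d = min(dist.items(), key=lambda kv: (kv[1], kv[0]))
        if d > cut:
            break
        merged = clusters.pop(ci) + clusters.pop(cj)
        heights.append(d)
        # unweighted average linkage: mean pairwise distance between members
        new_dist = {}
        for ck, members in clusters.items():
            s = sum(pd_mat[a, b] for a in merged for b in members)
            key = (min(ck, next_id), max(ck, next_id))
            new_dist[key] = s / (len(merged) * len(members))
        dist = {
            k: v for k, v in dist.items() if ci not in k and cj not in k
        }
        dist.update(new_dist)
        clusters[next_id] = merged
        next_id += 1

    labels = np.empty(n, dtype=int)
    # number clusters by their first member's position in the input order
    ordered = sorted(clusters.values(), key=min)
    for label, members in enumerate(ordered):
        for m in members:
            labels[m] = label
    return labels, heights


def cluster_pathways(
    pd_mat: np.ndarray, pathway_ids: list[str], cut: float = 0.55
) -> ClusterAssignment:
    """Flat average-linkage clustering of the PD matrix at height *cut*."""
    if pd_mat.shape != (len(pathway_ids), len(pathway_ids)):
        raise ValueError("PD matrix shape must match the pathway list")
    labels, heights = average_linkage_labels(pd_mat, cut)
    return ClusterAssignment(
        labels={pid: int(lab) for pid, lab in zip(pathway_ids, labels)},
        cut_height=cut,
        merge_heights=heights,
    )


def select_representatives(
    assignment: ClusterAssignment, p_final: dict[str, float]
) -> ClusterAssignment:
    """Flag, per cluster, the pathway with the smallest final p-value.

    Ties break to the lexicographically smallest pathway id.
    """
    missing = [p for p in assignment.labels if p not in p_final]
    if missing:
        raise ValueError(f"no final p-value for pathway(s): {missing[:5]}")
    reps: set[str] = set()
    for label in set(assignment.labels.values()):
        members = assignment.members(label)
        reps.add(min(members, key=lambda p: (p_final[p], p)))
    return ClusterAssignment(
        labels=dict(assignment.labels),
        representatives=reps,
        cut_height=assignment.cut_height,
        merge_heights=list(assignment.merge_heights),
    )


def cluster_enriched_pathways(
    merged_results, pathways, cut: float = 0.55
) -> ClusterAssignment | None:
    """End-to-end clustering of merged results using pathway gene sets.

    Pathway membership (G_i) comes from the pathway collection; the
    contributing-gene lists in the results are not used for OI.  Returns
    ``None`` when fewer than two pathways are available to cluster.
    """
    ids = [r.pathway_id for r in merged_results]
    if len(ids) < 2:
        return None
    by_id = {rec.pathway_id: rec.genes for rec in pathways}
    gene_sets = [frozenset(by_id[i]) for i in ids]
    oi = overlap_index_matrix(gene_sets)
    pd_mat = profile_distances(oi)
    assignment = cluster_pathways(pd_mat, ids, cut=cut)
    return select_representatives(
        assignment, {r.pathway_id: r.p_final for r in merged_results}
    )
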