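"""Cross-disorder comparison of significant gene sets.

Significant sets from the per-disorder screens are pooled (tagged with the
disorder they were significant in) and grouped by hierarchical clustering on
Jaccard distance; a cluster containing sets from two or more disorders is a
*shared* dysregulated gene set.  Candidate-gene enrichment of a set is an
upper-tail hypergeometric test against the analyzed-gene background.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from scipy.stats import hypergeom

__all__ = [
    "SharedSetCluster",
    "EnrichmentResult",
    "jaccard_distance",
    "cluster_shared_sets",
    "venn_counts",
    "hypergeom_enrichment",
    "overlap_gene_unions",
]


def jaccard_distance(a, b) -> float:
    """1 - |a & b| / |a | b| for nonempty finite sets."""
    a, b = set(a), set(b)
    if not a or not b:
        raise ValueError("Jaccard distance needs nonempty sets")
    return 1.0 - len(a & b) / len(a | b)


@dataclass
class SharedSetCluster:
    cluster_id: int
    member_sets: list            # (set name, disorder) pairs
    disorders: frozenset
    genes: frozenset             # union over member sets

    @property
    def shared(self) -> bool:
        return len(self.disorders) >= 2


def cluster_shared_sets(
    significant: dict,
    cut: float = 0.3,
    linkage: str = "average",
) -> tuple[list, np.ndarray | None]:
    """Group the per-disorder significant gene sets into clusters.

    ``significant`` maps a disorder name to an iterable of
    ``(set_name, members)`` pairs (or a GeneSetCollection).  Sets are pooled
    with their source disorder, the pairwise Jaccard distance matrix is
    clustered (average linkage by default) and the tree is cut at height
    ``cut``; merges at distance <= cut end up in one cluster.  Returns
    ``(clusters, linkage_matrix)`` — the linkage matrix (scipy format, None
    for a single set) doubles as the exportable dendrogram.
    """
    if not (0 < cut < 1):
        raise ValueError("cut must lie in (0, 1)")
    entries = []  # (set_name, disorder, members)
    for disorder, sets in significant.items():
        for item in sets:
            if isinstance(item, tuple):
                name, members = item
            else:  # GeneSet-like
                name, members = item.name, item.members
            members = frozenset(members)
            if not members:
                raise ValueError(f"set {name!r} has no members")
            entries.append((name, disorder, members))
    if not entries:
        raise ValueError("no significant sets to cluster")

    if len(entries) == 1:
        labels = np.array([1])
        Z = None
    else:
        m = len(entries)
        dist = np.zeros((m, m))
        for i, j in combinations(range(m), 2):
            d = jaccard_distance(entries[i][2], entries[j][2])
            dist[i, j] = dist[j, i] = d
        Z = hierarchy.linkage(squareform(dist, checks=False), method=linkage)
        labels = hierarchy.fcluster(Z, t=cut, criterion="distance")

    clusters = []
    for cid in sorted(set(labels)):
        idx = [i for i, l in enumerate(labels) if l == cid]
        members = [(entries[i][0], entries[i][1]) for i in idx]
        disorders = frozenset(entries[i][1] for i in idx)
        genes = frozenset().union(*(entries[i][2] for i in idx))
        clusters.append(SharedSetCluster(
            cluster_id=int(cid), member_sets=members,
            disorders=disorders, genes=genes,
        ))
    return clusters, Z


def venn_counts(clusters) -> dict:
    """Tally clusters by their exact disorder combination.

    Returns a dict mapping each nonempty combination (a sorted tuple of
    disorder names) to its cluster count; every combination over the
    disorders seen in the input is present, zeros included.  The counts sum
    to the number of clusters."""
    clusters = list(clusters)
    disorders = sorted(set().union(*(c.disorders for c in clusters))) if clusters else []
    out = {}
    for r in range(1, len(disorders) + 1):
        for combo in combinations(disorders, r):
            out[combo] = 0
    for c in clusters:
        key = tuple(sorted(c.disorders))
        out[key] = out.get(key, 0) + 1
    return out


@dataclass
class EnrichmentResult:
    set_name: str
    overlap: int                 # k: set genes also on the candidate list
    set_size: int                # set genes in the background
    candidate_size: int          # candidate genes in the background
    background_size: int
    p_hyper: float


def hypergeom_enrichment(
    set_genes,
    candidates,
    background,
    set_name: str = "",
) -> EnrichmentResult:
    """Upper-tail (inclusive) hypergeometric enrichment P(X >= k).

    The candidate list is intersected with the background first; the
    background is the analyzed-gene universe, not the genome."""
    bg = set(background)
    if len(set(set_genes)) > len(bg) or len(set(candidates)) > len(bg):
        raise ValueError("background smaller than one of the gene lists")
    sg = set(set_genes) & bg
    cand = set(candidates) & bg
    if not sg:
        raise ValueError("no set genes in the background")
    k = len(sg & cand)
    # P(X >= k) with margins (|bg|, |cand|, |sg|)
    p = float(hypergeom.sf(k - 1, len(bg), len(cand), len(sg)))
    return EnrichmentResult(
        set_name=set_name, overlap=k, set_size=len(sg),
        candidate_size=len(cand), background_size=len(bg),
        p_hyper=min(p, 1.0),
    )


def overlap_gene_unions(sets_a, sets_b) -> tuple[int, int, int]:
    """Sizes of the two gene unions and their intersection.

    ``sets_a`` / ``sets_b`` are iterables of gene sets (e.g. the shared
    aberrant clusters' gene unions and the shared co-expression modules'
    gene lists)."""
    sets_a, sets_b = list(sets_a), list(sets_b)
    if not sets_a or not sets_b:
        raise ValueError("both inputs must be nonempty")
    ua = set().union(*map(set, sets_a))
    ub = set().union(*map(set, sets_b))
    return len(ua), len(ub), len(ua & ub)
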