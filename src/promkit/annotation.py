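"""Genomic feature annotation of consensus clusters and the
primary/secondary promoter split.

Each cluster's dominant CTSS is placed relative to the nearest annotated TSS
(aTSS) and any overlapping gene bodies, and assigned the hierarchically
highest category:

    promoter > utr5 > utr3 > exon > intron > proximal > unassociated

where *promoter* is the window -500..+100 around the aTSS on the transcribed
strand, *proximal* is -1000..-501 (the shared -500 boundary belongs to
promoter), and clusters more than 1000 bp from the nearest aTSS and outside
any gene body are *unassociated*.  Per gene, the best-ranked (then nearest)
cluster becomes the primary promoter; all remaining clusters, and all
unassociated clusters, form the secondary set.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np

from .clustering import ConsensusCluster
from .io_formats import GeneModel

__all__ = [
    "CATEGORY_RANK",
    "FeatureAnnotation",
    "PromoterAssignment",
    "GeneIndex",
    "annotate_feature",
    "annotate_clusters",
    "split_primary_secondary",
    "tss_concordance",
]

#: Strict total order: lower rank = hierarchically higher.
CATEGORY_RANK = {
    "promoter": 0,
    "utr5": 1,
    "utr3": 2,
    "exon": 3,
    "intron": 4,
    "proximal": 5,
    "unassociated": 6,
}

PROMOTER_WINDOW = (-500, 100)
PROXIMAL_WINDOW = (-1000, -501)
UNASSOCIATED_CUTOFF = 1000


@dataclasses.dataclass
class FeatureAnnotation:
    """One cluster's gene assignment and genomic category."""

    cluster_id: str
    gene_id: str | None
    category: str
    signed_distance: int | None
    orientation: str | None  # sense / antisense relative to the assigned gene


@dataclasses.dataclass
class PromoterAssignment:
    """Per-gene promoter call: one primary cluster, ordered secondaries."""

    gene_id: str
    primary: str
    secondary: list[str]


class GeneIndex:
    """Nearest-aTSS and gene-body lookups over a set of gene models."""

    def __init__(self, genes: Sequence[GeneModel]):
        if not genes:
            raise ValueError("empty gene annotation set")
        self.genes = list(genes)
        self._by_chrom: dict[str, list[GeneModel]] = {}
        for g in self.genes:
            self._by_chrom.setdefault(g.chrom, []).append(g)
        self._atss: dict[str, tuple[np.ndarray, list[GeneModel]]] = {}
        for chrom, glist in self._by_chrom.items():
            glist_sorted = sorted(glist, key=lambda g: (g.aTSS, g.gene_id))
            atss = np.array([g.aTSS for g in glist_sorted], dtype=np.int64)
            self._atss[chrom] = (atss, glist_sorted)

    def nearest_by_atss(self, chrom: str, pos: int) -> GeneModel | None:
        """Gene with the smallest |signed distance| from ``pos`` to its aTSS
        (ties: smaller gene_id, for determinism)."""
        if chrom not in self._atss:
            return None
        atss, glist = self._atss[chrom]
        i = int(np.searchsorted(atss, pos))
        candidates = []
        for j in (i - 1, i, i + 1):
            if 0 <= j < len(glist):
                candidates.append(glist[j])
        return min(
            candidates,
            key=lambda g: (abs(g.signed_distance(pos)), g.gene_id),
        )

    def overlapping(self, chrom: str, pos: int) -> list[GeneModel]:
        """All genes whose span contains ``pos`` (either strand)."""
        return [g for g in self._by_chrom.get(chrom, []) if g.contains(pos)]


def annotate_feature(
    cluster: ConsensusCluster,
    index: GeneIndex,
    promoter_window: tuple[int, int] = PROMOTER_WINDOW,
    proximal_window: tuple[int, int] = PROXIMAL_WINDOW,
    unassociated_cutoff: int = UNASSOCIATED_CUTOFF,
) -> FeatureAnnotation:
    """Assign the hierarchically highest candidate category to one cluster.

    Candidates are the promoter/proximal windows of the nearest-aTSS gene
    plus the body features of every overlapping gene; gene assignment
    ignores strand (antisense clusters are assigned and flagged via
    ``orientation``).
    """
    pos = cluster.dominant_pos
    candidates: list[tuple[int, int, str, GeneModel]] = []  # (rank, |d|, cat, gene)

    nearest = index.nearest_by_atss(cluster.chrom, pos)
    if nearest is not None:
        d = nearest.signed_distance(pos)
        if promoter_window[0] <= d <= promoter_window[1]:
            candidates.append((CATEGORY_RANK["promoter"], abs(d), "promoter", nearest))
        elif proximal_window[0] <= d <= proximal_window[1]:
            candidates.append((CATEGORY_RANK["proximal"], abs(d), "proximal", nearest))

    for gene in index.overlapping(cluster.chrom, pos):
        cat = gene.feature_at(pos)
        if cat is not None:
            candidates.append(
                (CATEGORY_RANK[cat], abs(gene.signed_distance(pos)), cat, gene)
            )

    if not candidates:
        gene = nearest
        return FeatureAnnotation(
            cluster_id=cluster.cluster_id,
            gene_id=gene.gene_id if gene is not None else None,
            category="unassociated",
            signed_distance=gene.signed_distance(pos) if gene is not None else None,
            orientation=(
                ("sense" if cluster.strand == gene.strand else "antisense")
                if gene is not None
                else None
            ),
        )

    candidates.sort(key=lambda t: (t[0], t[1], t[3].gene_id))
    _, _, category, gene = candidates[0]
    return FeatureAnnotation(
        cluster_id=cluster.cluster_id,
        gene_id=gene.gene_id,
        category=category,
        signed_distance=gene.signed_distance(pos),
        orientation="sense" if cluster.strand == gene.strand else "antisense",
    )


def annotate_clusters(
    clusters: Sequence[ConsensusCluster],
    genes: Sequence[GeneModel],
    **kwargs,
) -> list[FeatureAnnotation]:
    index = GeneIndex(genes)
    return [annotate_feature(c, index, **kwargs) for c in clusters]


def split_primary_secondary(
    annotations: Sequence[FeatureAnnotation],
) -> tuple[list[PromoterAssignment], list[str]]:
    """Split annotated clusters into one primary promoter per gene plus the
    secondary set.

    Per gene, the primary is the cluster with the hierarchically highest
    category, ties broken by smaller |signed distance| (then cluster id);
    everything else — including every unassociated cluster — is secondary.
    """
    by_gene: dict[str, list[FeatureAnnotation]] = {}
    secondary: list[str] = []
    for ann in annotations:
        if ann.category == "unassociated" or ann.gene_id is None:
            secondary.append(ann.cluster_id)
        else:
            by_gene.setdefault(ann.gene_id, []).append(ann)

    assignments: list[PromoterAssignment] = []
    for gene_id in sorted(by_gene):
        anns = sorted(
            by_gene[gene_id],
            key=lambda a: (
                CATEGORY_RANK[a.category],
                abs(a.signed_distance) if a.signed_distance is not None else 1 << 40,
                a.cluster_id,
            ),
        )
        assignments.append(
            PromoterAssignment(
                gene_id=gene_id,
                primary=anns[0].cluster_id,
                secondary=[a.cluster_id for a in anns[1:]],
            )
        )
        secondary.extend(a.cluster_id for a in anns[1:])
    return assignments, sorted(secondary)


def tss_concordance(
    signed_distances: Sequence[int],
    thresholds: Sequence[int] = (20, 100, 500),
) -> dict[int, float]:
    """Cumulative fraction of genes whose dominant CTSS lies within each
    distance threshold of the aTSS.

    Only genes with |distance| <= max(thresholds) enter the denominator.
    Returns {threshold: fraction}; fractions are non-decreasing and reach
    1.0 at the largest threshold.
    """
    thresholds = sorted(thresholds)
    if not thresholds:
        raise ValueError("need at least one threshold")
    dist = np.abs(np.asarray(list(signed_distances), dtype=np.int64))
    dist = dist[dist <= thresholds[-1]]
    if dist.size == 0:
        raise ValueError("no genes within the maximum concordance threshold")
    return {t: float(np.mean(dist <= t)) for t in thresholds}
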