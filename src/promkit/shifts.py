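"""Developmental promoter-shift detection and gene-set overlap testing.

A promoter shift is a gene whose most-expressed tag cluster differs between
two developmental stages: the stage-wise dominant clusters must differ, each
must pass an expression floor in its own stage and dominate the other
cluster by a fold threshold, and at least one of the pair must sit in a
promoter, 5'UTR or promoter-proximal feature.  The consequence is *coding*
when the genomic interval between the two dominant positions touches the
CDS (potentially altering the protein), else *utr5_promoter*.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import scipy.stats

from .annotation import FeatureAnnotation
from .clustering import ConsensusCluster
from .io_formats import GeneModel

__all__ = [
    "ShiftCall",
    "OverlapTestResult",
    "SHIFT_ELEMENT_CATEGORIES",
    "detect_promoter_shifts",
    "classify_shift_consequence",
    "gene_set_overlap_test",
]

#: At least one cluster of a shift pair must carry one of these categories.
SHIFT_ELEMENT_CATEGORIES = frozenset({"promoter", "utr5", "proximal"})


@dataclasses.dataclass
class ShiftCall:
    """A gene-level alternative-promoter event between two stages."""

    gene_id: str
    stage_a: str
    stage_b: str
    cluster_a: str
    cluster_b: str
    pos_a: int
    pos_b: int
    shift_distance: int
    tpm_a_stage_a: float
    tpm_a_stage_b: float
    tpm_b_stage_a: float
    tpm_b_stage_b: float
    consequence: str = ""


def detect_promoter_shifts(
    clusters: Sequence[ConsensusCluster],
    annotations: Mapping[str, FeatureAnnotation],
    stage_a: str,
    stage_b: str,
    min_tpm: float = 0.5,
    min_fold: float = 2.0,
) -> list[ShiftCall]:
    """Call promoter shifts between two stages.

    Per gene with >= 2 consensus clusters, the dominant cluster of each
    stage is the one with the highest TPM in that stage.  A shift is called
    iff the two dominants differ, each has TPM >= ``min_tpm`` in its own
    stage, each is >= ``min_fold`` times more expressed than the other
    cluster within its own stage, and at least one of the pair is annotated
    as promoter, utr5 or proximal.  ``annotations`` maps cluster_id to its
    feature annotation.  Membership of the returned gene set is symmetric
    in the stage order.
    """
    by_gene: dict[str, list[ConsensusCluster]] = {}
    for c in clusters:
        ann = annotations.get(c.cluster_id)
        if ann is None or ann.gene_id is None or ann.category == "unassociated":
            continue
        by_gene.setdefault(ann.gene_id, []).append(c)

    calls: list[ShiftCall] = []
    for gene_id in sorted(by_gene):
        cands = by_gene[gene_id]
        if len(cands) < 2:
            continue
        dom_a = max(cands, key=lambda c: (c.tpm.get(stage_a, 0.0), -c.start))
        dom_b = max(cands, key=lambda c: (c.tpm.get(stage_b, 0.0), -c.start))
        if dom_a.cluster_id == dom_b.cluster_id:
            continue
        a_in_a = dom_a.tpm.get(stage_a, 0.0)
        a_in_b = dom_a.tpm.get(stage_b, 0.0)
        b_in_a = dom_b.tpm.get(stage_a, 0.0)
        b_in_b = dom_b.tpm.get(stage_b, 0.0)
        if a_in_a < min_tpm or b_in_b < min_tpm:
            continue
        if a_in_a < min_fold * b_in_a or b_in_b < min_fold * a_in_b:
            continue
        cat_a = annotations[dom_a.cluster_id].category
        cat_b = annotations[dom_b.cluster_id].category
        if not ({cat_a, cat_b} & SHIFT_ELEMENT_CATEGORIES):
            continue
        pos_a = dom_a.stage_dominant_pos.get(stage_a, dom_a.dominant_pos)
        pos_b = dom_b.stage_dominant_pos.get(stage_b, dom_b.dominant_pos)
        calls.append(
            ShiftCall(
                gene_id=gene_id,
                stage_a=stage_a,
                stage_b=stage_b,
                cluster_a=dom_a.cluster_id,
                cluster_b=dom_b.cluster_id,
                pos_a=pos_a,
                pos_b=pos_b,
                shift_distance=abs(pos_a - pos_b),
                tpm_a_stage_a=a_in_a,
                tpm_a_stage_b=a_in_b,
                tpm_b_stage_a=b_in_a,
                tpm_b_stage_b=b_in_b,
            )
        )
    return calls


def classify_shift_consequence(shift: ShiftCall, gene: GeneModel | None) -> str:
    """'coding' iff the interval between the two dominant positions
    (exclusive of the downstream-most TSS base itself) intersects the CDS;
    otherwise 'utr5_promoter'.  Genes without a CDS are 'utr5_promoter'.
    """
    if gene is None or not gene.cds:
        return "utr5_promoter"
    lo, hi = sorted((shift.pos_a, shift.pos_b))
    # exclude the downstream-most TSS base (transcribed-strand downstream)
    if gene.strand == "+":
        hi -= 1
    else:
        lo += 1
    if lo > hi:
        return "utr5_promoter"
    for s, e in gene.cds:
        if s <= hi and e >= lo:
            return "coding"
    return "utr5_promoter"


@dataclasses.dataclass
class OverlapTestResult:
    """Two-sided Fisher's exact test of the overlap between two gene sets."""

    n_a: int
    n_b: int
    n_overlap: int
    universe: int
    odds_ratio: float
    p_value: float


def gene_set_overlap_test(
    set_a: set[str], set_b: set[str], universe: set[str]
) -> OverlapTestResult:
    """Fisher's exact test on the 2x2 table
    [[|A∩B|, |A\\B|], [|B\\A|, |U\\(A∪B)|]] (two-sided, hypergeometric)."""
    if not set_a <= universe or not set_b <= universe:
        raise ValueError("both sets must be subsets of the universe")
    n_ab = len(set_a & set_b)
    n_a_only = len(set_a - set_b)
    n_b_only = len(set_b - set_a)
    n_neither = len(universe) - len(set_a | set_b)
    odds_ratio, p = scipy.stats.fisher_exact(
        [[n_ab, n_a_only], [n_b_only, n_neither]], alternative="two-sided"
    )
    return OverlapTestResult(
        n_a=len(set_a),
        n_b=len(set_b),
        n_overlap=n_ab,
        universe=len(universe),
        odds_ratio=float(odds_ratio),
        p_value=float(p),
    )
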