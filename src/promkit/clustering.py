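"""Distance-based CTSS clustering, quantification and consensus aggregation.

Turns per-position capped-5' counts into tag clusters (TCs), applies the
expression filters, and merges per-stage TCs into cross-stage consensus
clusters:

* neighbouring CTSSs with mutual distance < 20 bp merge into one TC;
* each TC carries its tag count, TPM, dominant CTSS and interquantile
  width (IQW, the span between the 0.1 and 0.9 cumulative-tag quantiles);
* TCs with TPM < 0.1 are discarded, as are single-position TCs
  ("singletons") with TPM < 5;
* TCs from different stages with inter-interval gap < 100 bp merge into a
  consensus cluster with per-stage TPMs.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import CtssTable

__all__ = [
    "TagCluster",
    "ConsensusCluster",
    "normalize_tpm",
    "cluster_ctss_distclu",
    "quantify_cluster",
    "cluster_and_quantify",
    "filter_clusters",
    "replicate_consistency_filter",
    "aggregate_consensus",
    "tag_clusters_to_frame",
]


@dataclasses.dataclass
class TagCluster:
    """A contiguous TSS region in one sample, with tag quantification."""

    chrom: str
    strand: str
    start: int
    end: int
    sample: str
    tag_count: int
    tpm: float
    dominant_pos: int
    dominant_count: int
    q_low_pos: int
    q_up_pos: int
    iqw: int
    positions: np.ndarray = dataclasses.field(default=None, repr=False, compare=False)
    counts: np.ndarray = dataclasses.field(default=None, repr=False, compare=False)

    @property
    def width(self) -> int:
        return self.end - self.start + 1


@dataclasses.dataclass
class ConsensusCluster:
    """Cross-stage union of overlapping/nearby TCs: one promoter region."""

    chrom: str
    strand: str
    start: int
    end: int
    members: dict[str, list[TagCluster]]
    tpm: dict[str, float]
    stage_dominant_pos: dict[str, int]
    dominant_pos: int
    dominant_stage: str
    iqw: int
    cluster_id: str = ""

    @property
    def total_tpm(self) -> float:
        return float(sum(self.tpm.values()))


def normalize_tpm(table: CtssTable) -> pd.DataFrame:
    """Per-position tags-per-million: count * 1e6 / library_size."""
    if table.library_size <= 0:
        raise ValueError("library_size must be > 0 for TPM normalization")
    df = table.df.copy()
    df["tpm"] = df["count"] * 1e6 / table.library_size
    return df


def cluster_ctss_distclu(
    positions: np.ndarray, max_dist: int = 20
) -> list[tuple[int, int]]:
    """Group sorted positions into clusters: consecutive CTSSs belong to the
    same cluster iff their position difference is strictly below ``max_dist``.

    Returns (start_index, end_index) index slices into the sorted position
    array, one per cluster, in genomic order.  Duplicate positions are an
    error; unsorted input is sorted internally by the caller contract.
    """
    if max_dist < 1:
        raise ValueError("max_dist must be >= 1")
    positions = np.asarray(positions)
    if positions.size == 0:
        return []
    if np.any(np.diff(positions) == 0):
        raise ValueError("duplicate CTSS positions within one sample/strand")
    breaks = np.flatnonzero(np.diff(positions) >= max_dist) + 1
    bounds = np.concatenate([[0], breaks, [positions.size]])
    return [(int(s), int(e)) for s, e in zip(bounds[:-1], bounds[1:])]


def quantify_cluster(
    positions: np.ndarray,
    counts: np.ndarray,
    strand: str,
    chrom: str = "",
    sample: str = "",
    library_size: int = 0,
    q_low: float = 0.1,
    q_up: float = 0.9,
) -> TagCluster:
    """Quantify one cluster of member CTSSs.

    * dominant position = max count, ties broken 5'-most on the transcribed
      strand;
    * quantile positions are the 5'-most positions (in transcribed order)
      where the cumulative tag fraction reaches ``q_low`` / ``q_up``;
    * IQW = |q_up_pos - q_low_pos| + 1.
    """
    positions = np.asarray(positions, dtype=np.int64)
    counts = np.asarray(counts, dtype=np.int64)
    if positions.size == 0:
        raise ValueError("cannot quantify an empty cluster")
    if not 0 <= q_low <= q_up <= 1:
        raise ValueError("require 0 <= q_low <= q_up <= 1")
    order = np.argsort(positions)
    positions, counts = positions[order], counts[order]
    if strand == "-":
        # transcribed order is decreasing genomic coordinate
        tpos, tcounts = positions[::-1], counts[::-1]
    else:
        tpos, tcounts = positions, counts
    total = int(counts.sum())
    # dominant: max count, tie -> 5'-most on the transcribed strand
    dom_idx = int(np.argmax(tcounts))
    dominant_pos = int(tpos[dom_idx])
    dominant_count = int(tcounts[dom_idx])
    cum = np.cumsum(tcounts)
    eps = 1e-9
    q_low_pos = int(tpos[int(np.searchsorted(cum, q_low * total - eps))])
    q_up_pos = int(tpos[int(np.searchsorted(cum, q_up * total - eps))])
    iqw = abs(q_up_pos - q_low_pos) + 1
    tpm = total * 1e6 / library_size if library_size > 0 else 0.0
    return TagCluster(
        chrom=chrom,
        strand=strand,
        start=int(positions[0]),
        end=int(positions[-1]),
        sample=sample,
        tag_count=total,
        tpm=float(tpm),
        dominant_pos=dominant_pos,
        dominant_count=dominant_count,
        q_low_pos=q_low_pos,
        q_up_pos=q_up_pos,
        iqw=int(iqw),
        positions=positions,
        counts=counts,
    )


def cluster_and_quantify(
    table: CtssTable,
    sample: str = "",
    max_dist: int = 20,
    q_low: float = 0.1,
    q_up: float = 0.9,
) -> list[TagCluster]:
    """Run distance clustering per (chrom, strand) and quantify every TC."""
    clusters: list[TagCluster] = []
    for (chrom, strand), group in table.df.groupby(["chrom", "strand"], sort=True):
        pos = group["pos"].to_numpy()
        cnt = group["count"].to_numpy()
        order = np.argsort(pos)
        pos, cnt = pos[order], cnt[order]
        for s, e in cluster_ctss_distclu(pos, max_dist=max_dist):
            clusters.append(
                quantify_cluster(
                    pos[s:e],
                    cnt[s:e],
                    strand=strand,
                    chrom=chrom,
                    sample=sample,
                    library_size=table.library_size,
                    q_low=q_low,
                    q_up=q_up,
                )
            )
    clusters.sort(key=lambda c: (c.chrom, c.strand, c.start))
    return clusters


def filter_clusters(
    clusters: Sequence[TagCluster],
    tpm_min: float = 0.1,
    singleton_tpm_min: float = 5.0,
) -> list[TagCluster]:
    """Expression filters: drop TCs with TPM below ``tpm_min`` and
    single-position TCs with TPM below ``singleton_tpm_min``."""
    return [
        c
        for c in clusters
        if c.tpm >= tpm_min and (c.width > 1 or c.tpm >= singleton_tpm_min)
    ]


def _covered_fraction(region: tuple[int, int], others: Sequence[tuple[int, int]]) -> float:
    """Largest fraction of ``region`` covered by any single interval in
    ``others``."""
    s, e = region
    length = e - s + 1
    best = 0
    for os, oe in others:
        ov = min(e, oe) - max(s, os) + 1
        if ov > best:
            best = ov
    return max(best, 0) / length


def replicate_consistency_filter(
    regions_rep1: Sequence[tuple[int, int]],
    regions_rep2: Sequence[tuple[int, int]],
    min_fraction: float = 0.9,
) -> list[tuple[int, int]]:
    """Keep regions reproducible between replicates.

    A region from one replicate is kept iff some region of the other
    replicate covers at least ``min_fraction`` of its length (checked
    reciprocally); the union of kept regions is returned, merged.  Regions
    are (start, end) 1-based inclusive intervals on one chrom/strand.
    """
    if not 0 < min_fraction <= 1:
        raise ValueError("min_fraction must be in (0, 1]")
    kept = [r for r in regions_rep1 if _covered_fraction(r, regions_rep2) >= min_fraction]
    kept += [r for r in regions_rep2 if _covered_fraction(r, regions_rep1) >= min_fraction]
    if not kept:
        return []
    kept.sort()
    merged = [list(kept[0])]
    for s, e in kept[1:]:
        if s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [tuple(m) for m in merged]


def aggregate_consensus(
    tc_sets_by_stage: Mapping[str, Sequence[TagCluster]],
    max_gap: int = 100,
    q_low: float = 0.1,
    q_up: float = 0.9,
) -> list[ConsensusCluster]:
    """Single-linkage merge of per-stage TCs into consensus clusters.

    Two TC intervals chain together iff the gap between their nearest ends
    is strictly below ``max_gap`` bases.  Per-stage TPM is the sum of member
    TPMs for that stage (0 when the stage contributed no TC); the overall
    dominant position comes from the stage with the highest TPM (ties broken
    by lexicographic stage name, making the result independent of the order
    in which stages are supplied).
    """
    entries: list[tuple[str, str, int, int, str, TagCluster]] = []
    for stage, tcs in tc_sets_by_stage.items():
        for tc in tcs:
            entries.append((tc.chrom, tc.strand, tc.start, tc.end, stage, tc))
    entries.sort(key=lambda t: (t[0], t[1], t[2], t[3], t[4]))

    consensus: list[ConsensusCluster] = []
    group: list[tuple[str, TagCluster]] = []
    group_key: tuple[str, str] | None = None
    group_end = -1

    def _flush() -> None:
        if not group:
            return
        chrom, strand = group_key
        members: dict[str, list[TagCluster]] = {}
        for stage, tc in group:
            members.setdefault(stage, []).append(tc)
        stages = sorted(tc_sets_by_stage)
        tpm = {
            s: float(sum(tc.tpm for tc in members.get(s, []))) for s in stages
        }
        stage_dominant: dict[str, int] = {}
        for s in stages:
            if members.get(s):
                # dominant TC of the stage = member with max TPM
                best = max(members[s], key=lambda tc: (tc.tpm, -tc.start))
                stage_dominant[s] = best.dominant_pos
        present = [s for s in stages if s in stage_dominant]
        dominant_stage = max(present, key=lambda s: (tpm[s], s))
        # recompute the quantile width over the pooled member CTSSs of the
        # dominant stage so the consensus IQW reflects one sample's shape
        dom_members = members[dominant_stage]
        pos = np.concatenate([tc.positions for tc in dom_members])
        cnt = np.concatenate([tc.counts for tc in dom_members])
        qc = quantify_cluster(pos, cnt, strand=strand, chrom=chrom, q_low=q_low, q_up=q_up)
        consensus.append(
            ConsensusCluster(
                chrom=chrom,
                strand=strand,
                start=min(tc.start for _, tc in group),
                end=max(tc.end for _, tc in group),
                members=members,
                tpm=tpm,
                stage_dominant_pos=stage_dominant,
                dominant_pos=stage_dominant[dominant_stage],
                dominant_stage=dominant_stage,
                iqw=qc.iqw,
            )
        )

    for chrom, strand, start, end, stage, tc in entries:
        key = (chrom, strand)
        if group_key == key and (start - group_end - 1) < max_gap:
            group.append((stage, tc))
            group_end = max(group_end, end)
        else:
            _flush()
            group = [(stage, tc)]
            group_key = key
            group_end = end
    _flush()
    consensus.sort(key=lambda c: (c.chrom, c.strand, c.start))
    for i, c in enumerate(consensus, 1):
        c.cluster_id = f"CC{i:05d}"
    return consensus


def tag_clusters_to_frame(clusters: Sequence[TagCluster]) -> pd.DataFrame:
    """Flatten TCs into a DataFrame with all quantification columns."""
    return pd.DataFrame(
        {
            "chrom": [c.chrom for c in clusters],
            "strand": [c.strand for c in clusters],
            "start": [c.start for c in clusters],
            "end": [c.end for c in clusters],
            "sample": [c.sample for c in clusters],
            "tag_count": [c.tag_count for c in clusters],
            "tpm": [c.tpm for c in clusters],
            "dominant_pos": [c.dominant_pos for c in clusters],
            "dominant_count": [c.dominant_count for c in clusters],
            "q_low_pos": [c.q_low_pos for c in clusters],
            "q_up_pos": [c.q_up_pos for c in clusters],
            "iqw": [c.iqw for c in clusters],
        }
    )
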