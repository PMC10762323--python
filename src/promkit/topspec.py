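"""5' terminal oligopyrimidine (TOP) scoring and tau tissue specificity.

The TOP motif is a cap-adjacent cytosine followed by a pyrimidine run; TOP
mRNAs are candidate targets of TOR-dependent translational control.  The
gene-level TOPscore is the read-fraction-weighted pyrimidine tract length
over the CTSSs of the gene's primary tag cluster; genes with TOPscore
strictly greater than 3 carry the candidate TOP signature.

tau is the standard tissue-specificity index on an expression matrix:
tau = sum(1 - x_hat_i) / (n - 1) with x_hat the per-tissue expression
normalized by the maximum after a log2(x + 1) transform (configurable to
identity); tau is 0 for uniform expression and 1 for single-tissue
expression.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd

from .io_formats import GenomeSequence

__all__ = [
    "TopScoreRecord",
    "SpecificityRecord",
    "tss_top_length",
    "gene_topscore",
    "tau_specificity",
    "tau_table",
    "TRACT_CAP",
    "TOP_THRESHOLD",
]

#: Maximum measurable pyrimidine tract length (window-bounded).
TRACT_CAP = 41

#: TOPscore above which a gene is a candidate TOP mRNA (strict inequality).
TOP_THRESHOLD = 3.0


@dataclasses.dataclass
class TopScoreRecord:
    gene_id: str
    topscore: float
    contributions: list[tuple[int, float, int]]  # (pos, read fraction, tract length)

    @property
    def is_top_candidate(self) -> bool:
        return self.topscore > TOP_THRESHOLD


@dataclasses.dataclass
class SpecificityRecord:
    gene_id: str
    tau: float | None  # None = undefined (all-zero expression), flagged
    n_tissues: int
    max_tissue: str | None


def tss_top_length(
    genome: GenomeSequence,
    chrom: str,
    pos: int,
    strand: str,
    cap: int = TRACT_CAP,
) -> int:
    """Pyrimidine tract length at one TSS on the transcribed strand.

    0 unless the TSS base is C; otherwise the length of the maximal run of
    pyrimidines (C/T) starting at the TSS, capped at ``cap`` nt.  An N
    terminates the run.
    """
    length = genome.lengths[chrom]
    if strand == "+":
        end = min(pos + cap - 1, length)
        seq = genome.fetch(chrom, pos, end, "+")
    else:
        start = max(pos - cap + 1, 1)
        seq = genome.fetch(chrom, start, pos, "-")
    if not seq or seq[0] != "C":
        return 0
    run = 0
    for base in seq:
        if base in "CT":
            run += 1
        else:
            break
    return run


def gene_topscore(
    gene_id: str,
    ctss: Sequence[tuple[str, int, str, int]],
    genome: GenomeSequence,
    cap: int = TRACT_CAP,
) -> TopScoreRecord:
    """Read-fraction-weighted tract length over a gene's primary-cluster
    CTSSs: topscore = sum_i (count_i / total) * tract_length_i.

    Invariant to rescaling all counts by a constant; requires total > 0.
    """
    total = sum(count for _, _, _, count in ctss)
    if total <= 0:
        raise ValueError(f"{gene_id}: zero total CTSS count")
    contributions = []
    score = 0.0
    for chrom, pos, strand, count in ctss:
        frac = count / total
        tract = tss_top_length(genome, chrom, pos, strand, cap=cap)
        contributions.append((pos, frac, tract))
        score += frac * tract
    return TopScoreRecord(gene_id=gene_id, topscore=score, contributions=contributions)


_TRANSFORMS = {
    "log2p1": lambda x: np.log2(x + 1.0),
    "identity": lambda x: x,
}


def tau_specificity(
    expression: Sequence[float],
    tissues: Sequence[str] | None = None,
    transform: str = "log2p1",
    gene_id: str = "",
) -> SpecificityRecord:
    """tau tissue-specificity index of one gene's expression row.

    tau = sum(1 - x_hat_i) / (n - 1) with x_hat_i = t(x_i) / max_j t(x_j);
    all-zero rows yield tau = None (undefined, flagged).
    """
    x = np.asarray(list(expression), dtype=float)
    if x.size < 2:
        raise ValueError("tau requires at least 2 tissues")
    if np.any(x < 0):
        raise ValueError("negative expression values")
    if transform not in _TRANSFORMS:
        raise ValueError(f"unknown transform {transform!r}")
    names = list(tissues) if tissues is not None else [str(i) for i in range(x.size)]
    t = _TRANSFORMS[transform](x)
    m = t.max()
    if m == 0:
        return SpecificityRecord(
            gene_id=gene_id, tau=None, n_tissues=x.size, max_tissue=None
        )
    xhat = t / m
    tau = float(np.sum(1.0 - xhat) / (x.size - 1))
    return SpecificityRecord(
        gene_id=gene_id,
        tau=tau,
        n_tissues=int(x.size),
        max_tissue=names[int(np.argmax(t))],
    )


def tau_table(matrix: pd.DataFrame, transform: str = "log2p1") -> pd.DataFrame:
    """tau per row of a genes x tissues expression matrix."""
    records = []
    for gene_id, row in matrix.iterrows():
        rec = tau_specificity(
            row.to_numpy(), tissues=list(matrix.columns),
            transform=transform, gene_id=str(gene_id),
        )
        records.append(
            {
                "gene_id": rec.gene_id,
                "tau": np.nan if rec.tau is None else rec.tau,
                "n_tissues": rec.n_tissues,
                "max_tissue": rec.max_tissue,
            }
        )
    return pd.DataFrame(records)
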