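"""Core-promoter sequence features around dominant CTSSs.

Extracts strand-aware -50..+50 windows anchored at the dominant CTSS
(offsets skip zero; the TSS base is +1), and computes:

* the initiator class from the (-1, +1) dinucleotide (CA / CG / TG /
  other-PyPu / non-PyPu);
* position-weight-matrix scans with *exact* p-values obtained by
  dynamic-programming convolution of integer-scaled log-odds scores over
  the background distribution (the construction used by FIMO);
* a strand-specific TATA-box scan (default p <= 1e-4) and a dual-matrix
  Y-patch scan (consensus CTTCTTCCTC and its reverse complement);
* positional hit profiles, per-offset dinucleotide frequency matrices and
  per-offset base frequencies (logo data);
* a rule-based architecture label (TATA status x initiator x Y-patch);
* transposable-element overlap fractions for +/-50 bp TSS windows.
"""

from __future__ import annotations

import dataclasses
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import GenomeSequence, IntervalRecord, revcomp

__all__ = [
    "PromoterWindow",
    "PositionWeightMatrix",
    "MotifHit",
    "ArchitectureLabel",
    "offset_to_index",
    "index_to_offset",
    "extract_window",
    "initiator_class",
    "build_pwm",
    "load_pwm",
    "default_tata_pwm",
    "ypatch_pwm",
    "pwm_scan",
    "ypatch_scan",
    "motif_position_profile",
    "dinucleotide_matrix",
    "base_frequency_matrix",
    "classify_architecture",
    "te_overlap_fraction",
    "TATA_FAMILY",
    "YPATCH_CONSENSUS",
]

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}

#: Consensus family of the shipped default TATA matrix (W = A/T).
TATA_FAMILY = tuple(
    f"TATA{w1}A{w2}A" for w1 in "AT" for w2 in "AT"
)

YPATCH_CONSENSUS = "CTTCTTCCTC"


def offset_to_index(offset: int, flank: int) -> int:
    """Map a skip-zero TSS-relative offset to a window string index."""
    if offset == 0:
        raise ValueError("offset 0 does not exist; the TSS base is +1")
    return offset + flank if offset < 0 else offset + flank - 1


def index_to_offset(index: int, flank: int) -> int:
    """Inverse of :func:`offset_to_index`."""
    return index - flank if index < flank else index - flank + 1


@dataclasses.dataclass
class PromoterWindow:
    """Transcribed-strand sequence around a dominant CTSS.

    ``seq`` has length ``2 * flank + 1``; ``base(+1)`` is the TSS base.
    """

    seq: str
    flank: int
    chrom: str = ""
    dominant_pos: int = 0
    strand: str = "+"
    cluster_id: str = ""

    def __post_init__(self) -> None:
        if len(self.seq) != 2 * self.flank + 1:
            raise ValueError(
                f"window length {len(self.seq)} != 2*flank+1 = {2 * self.flank + 1}"
            )

    def base(self, offset: int) -> str:
        return self.seq[offset_to_index(offset, self.flank)]

    def subseq(self, start_offset: int, length: int) -> str:
        i = offset_to_index(start_offset, self.flank)
        return self.seq[i : i + length]


def extract_window(
    genome: GenomeSequence,
    chrom: str,
    dominant_pos: int,
    strand: str,
    flank: int = 50,
    cluster_id: str = "",
) -> PromoterWindow | None:
    """Extract the +/-``flank`` window around a dominant CTSS.

    Minus-strand windows are reverse-complemented so that offset +1 is the
    TSS base on the transcribed strand in both cases.  Returns ``None``
    when the window would cross a contig edge (callers should warn and
    skip the cluster).
    """
    length = genome.lengths[chrom]
    if dominant_pos - flank < 1 or dominant_pos + flank > length:
        return None
    seq = genome.fetch(chrom, dominant_pos - flank, dominant_pos + flank, strand)
    return PromoterWindow(
        seq=seq,
        flank=flank,
        chrom=chrom,
        dominant_pos=dominant_pos,
        strand=strand,
        cluster_id=cluster_id,
    )


def initiator_class(window: PromoterWindow) -> tuple[str, bool]:
    """Initiator class from the (-1, +1) dinucleotide.

    Returns ``(class, ambiguous)`` where class is one of CA, CG, TG,
    other-PyPu, non-PyPu; an N at either offset yields non-PyPu with the
    ambiguity flag set.
    """
    m1, p1 = window.base(-1), window.base(+1)
    if "N" in (m1, p1):
        return "non-PyPu", True
    dinuc = m1 + p1
    if dinuc in ("CA", "CG", "TG"):
        return dinuc, False
    if m1 in "CT" and p1 in "AG":
        return "other-PyPu", False
    return "non-PyPu", False


# ---------------------------------------------------------------------------
# position weight matrices with exact p-values
# ---------------------------------------------------------------------------


class _ScoreDistribution:
    """Exact null distribution of integer PWM scores under the background.

    Built by convolving the per-position score distributions; ``pvalue(s)``
    is the probability that a random background sequence of motif length
    scores >= s.
    """

    def __init__(self, int_scores: np.ndarray, background: np.ndarray):
        probs = np.zeros(1)
        probs[0] = 1.0
        offset = 0  # probs[k] is P(total == offset + k)
        for row in int_scores:
            smin, smax = int(row.min()), int(row.max())
            new = np.zeros(len(probs) + smax - smin)
            for b in range(4):
                shift = int(row[b]) - smin
                new[shift : shift + len(probs)] += background[b] * probs
            probs = new
            offset += smin
        self.offset = offset
        self.sf = np.concatenate(
            [np.cumsum(probs[::-1])[::-1], [0.0]]
        )  # sf[k] = P(total >= offset + k)

    def pvalue(self, int_score: int) -> float:
        k = int_score - self.offset
        if k <= 0:
            return 1.0
        if k >= len(self.sf):
            return 0.0
        return float(self.sf[k])


@dataclasses.dataclass
class PositionWeightMatrix:
    """Pseudocounted base probabilities per motif position plus background.

    The log-odds matrix (base 2) is derived from both; exact p-values use
    log-odds scores scaled by ``scale`` and rounded to integers.
    """

    name: str
    probs: np.ndarray  # (L, 4), rows sum to 1, column order ACGT
    background: np.ndarray = dataclasses.field(
        default_factory=lambda: np.full(4, 0.25)
    )
    scale: int = 1000

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.probs.ndim != 2 or self.probs.shape[1] != 4:
            raise ValueError("probs must be an (L, 4) matrix")
        if self.length < 4:
            raise ValueError("motif length must be >= 4")
        if not np.allclose(self.probs.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError("each PWM position's probabilities must sum to 1")
        if not np.allclose(self.background.sum(), 1.0, atol=1e-6):
            raise ValueError("background must sum to 1")
        self._dist: _ScoreDistribution | None = None

    @property
    def length(self) -> int:
        return self.probs.shape[0]

    @property
    def log_odds(self) -> np.ndarray:
        return np.log2(self.probs / self.background)

    @property
    def int_scores(self) -> np.ndarray:
        return np.rint(self.log_odds * self.scale).astype(np.int64)

    @property
    def distribution(self) -> _ScoreDistribution:
        if self._dist is None:
            self._dist = _ScoreDistribution(self.int_scores, self.background)
        return self._dist

    def int_score(self, seq: str) -> int | None:
        """Integer-scaled log-odds score of ``seq``; None if ambiguous."""
        if len(seq) != self.length:
            raise ValueError("sequence length must equal motif length")
        total = 0
        scores = self.int_scores
        for i, base in enumerate(seq):
            b = _BASE_INDEX.get(base)
            if b is None:
                return None
            total += int(scores[i, b])
        return total

    def pvalue(self, int_score: int) -> float:
        return self.distribution.pvalue(int_score)

    def reverse_complement(self) -> "PositionWeightMatrix":
        return PositionWeightMatrix(
            name=self.name + "_rc",
            probs=self.probs[::-1, ::-1].copy(),
            background=self.background.copy(),
            scale=self.scale,
        )


def build_pwm(
    aligned_sequences: Sequence[str],
    pseudocount: float = 0.25,
    background: np.ndarray | None = None,
    name: str = "pwm",
) -> PositionWeightMatrix:
    """Build a PWM from >= 2 equal-length ungapped sequences.

    probabilities = (count + pseudocount) / (n + 4 * pseudocount).
    """
    if len(aligned_sequences) < 2:
        raise ValueError("need at least 2 aligned sequences")
    lengths = {len(s) for s in aligned_sequences}
    if len(lengths) != 1:
        raise ValueError("aligned sequences must have equal length")
    (length,) = lengths
    counts = np.zeros((length, 4), dtype=float)
    for seq in aligned_sequences:
        for i, base in enumerate(seq.upper()):
            if base not in _BASE_INDEX:
                raise ValueError(f"invalid base {base!r} in aligned sequences")
            counts[i, _BASE_INDEX[base]] += 1
    n = len(aligned_sequences)
    probs = (counts + pseudocount) / (n + 4 * pseudocount)
    bg = np.full(4, 0.25) if background is None else np.asarray(background, float)
    return PositionWeightMatrix(name=name, probs=probs, background=bg)


def _pwm_from_counts(
    counts: np.ndarray,
    pseudocount: float = 0.25,
    background: np.ndarray | None = None,
    name: str = "pwm",
) -> PositionWeightMatrix:
    counts = np.asarray(counts, dtype=float)
    n = counts.sum(axis=1, keepdims=True)
    probs = (counts + pseudocount) / (n + 4 * pseudocount)
    bg = np.full(4, 0.25) if background is None else np.asarray(background, float)
    return PositionWeightMatrix(name=name, probs=probs, background=bg)


def load_pwm(
    path: str | Path,
    pseudocount: float = 0.25,
    background: np.ndarray | None = None,
) -> PositionWeightMatrix:
    """Load a PWM from JASPAR PFM (counts) or MEME minimal (probabilities).

    JASPAR counts get the pseudocount treatment of :func:`build_pwm`; MEME
    probability matrices get a small probability floor so log-odds stay
    finite.
    """
    text = Path(path).read_text()
    if "MEME version" in text:
        return _load_meme(text, name=Path(path).stem, background=background)
    return _load_jaspar(text, pseudocount=pseudocount, background=background)


def _load_jaspar(
    text: str, pseudocount: float, background: np.ndarray | None
) -> PositionWeightMatrix:
    name = "pwm"
    rows: dict[str, list[float]] = {}
    for line in text.splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith(">"):
            name = line[1:].split()[0]
            continue
        base = line[0].upper()
        if base not in _BASE_INDEX:
            raise ValueError(f"malformed JASPAR line: {line!r}")
        nums = line[1:].replace("[", " ").replace("]", " ").split()
        rows[base] = [float(x) for x in nums]
    if sorted(rows) != list("ACGT"):
        raise ValueError("JASPAR matrix must have A/C/G/T rows")
    counts = np.array([rows[b] for b in BASES]).T  # (L, 4)
    return _pwm_from_counts(
        counts, pseudocount=pseudocount, background=background, name=name
    )


def _load_meme(
    text: str, name: str, background: np.ndarray | None
) -> PositionWeightMatrix:
    lines = iter(text.splitlines())
    probs_rows: list[list[float]] = []
    in_matrix = False
    for line in lines:
        stripped = line.strip()
        if stripped.startswith("MOTIF"):
            parts = stripped.split()
            if len(parts) > 1:
                name = parts[1]
        elif stripped.startswith("letter-probability matrix"):
            in_matrix = True
        elif in_matrix:
            if not stripped:
                break
            fields = stripped.split()
            if len(fields) < 4:
                break
            probs_rows.append([float(x) for x in fields[:4]])
    if not probs_rows:
        raise ValueError("no letter-probability matrix found in MEME file")
    probs = np.asarray(probs_rows)
    floor = 1e-3
    probs = (probs + floor) / (1 + 4 * floor)
    bg = np.full(4, 0.25) if background is None else np.asarray(background, float)
    return PositionWeightMatrix(name=name, probs=probs, background=bg)


_DEFAULT_TATA: PositionWeightMatrix | None = None
_YPATCH: PositionWeightMatrix | None = None


def default_tata_pwm() -> PositionWeightMatrix:
    """The shipped canonical plant TATA-box matrix (TATAWAWA family).

    Built from the four consensus-family members with pseudocount 0.25;
    any user matrix in JASPAR/MEME format can be substituted via
    :func:`load_pwm`.
    """
    global _DEFAULT_TATA
    if _DEFAULT_TATA is None:
        path = resources.files("promkit").joinpath("data/tata_tatawawa.jaspar")
        _DEFAULT_TATA = _load_jaspar(path.read_text(), pseudocount=0.25, background=None)
    return _DEFAULT_TATA


def ypatch_pwm() -> PositionWeightMatrix:
    """PWM built from the Y-patch 10-mer consensus (pseudocount 0.25)."""
    global _YPATCH
    if _YPATCH is None:
        counts = np.zeros((len(YPATCH_CONSENSUS), 4))
        for i, base in enumerate(YPATCH_CONSENSUS):
            counts[i, _BASE_INDEX[base]] = 1
        _YPATCH = _pwm_from_counts(counts, pseudocount=0.25, name="ypatch")
    return _YPATCH


@dataclasses.dataclass
class MotifHit:
    """A PWM match inside a promoter window (window offset coordinates)."""

    motif: str
    start_offset: int
    score: float
    p_value: float
    cluster_id: str = ""
    scan_strand: str = "+"


def pwm_scan(
    window: PromoterWindow,
    pwm: PositionWeightMatrix,
    p_threshold: float = 1e-4,
    scan_strand: str = "+",
) -> list[MotifHit]:
    """Scan the window's transcribed strand with one PWM.

    Reports every start offset whose exact p-value (probability that a
    random background sequence of motif length scores at least as high)
    is <= ``p_threshold``.  Ambiguous-base placements are skipped.
    """
    L = pwm.length
    if L > len(window.seq):
        raise ValueError("motif longer than window")
    hits: list[MotifHit] = []
    for i in range(len(window.seq) - L + 1):
        s = pwm.int_score(window.seq[i : i + L])
        if s is None:
            continue
        p = pwm.pvalue(s)
        if p <= p_threshold:
            hits.append(
                MotifHit(
                    motif=pwm.name,
                    start_offset=index_to_offset(i, window.flank),
                    score=s / pwm.scale,
                    p_value=p,
                    cluster_id=window.cluster_id,
                    scan_strand=scan_strand,
                )
            )
    return hits


def ypatch_scan(
    window: PromoterWindow, p_threshold: float = 1e-4
) -> list[MotifHit]:
    """Scan for the Y patch with both the consensus-strand matrix and its
    reverse complement (GAGGAAGAAG), merging hits per offset."""
    fwd = ypatch_pwm()
    hits = pwm_scan(window, fwd, p_threshold, scan_strand="+")
    rc_hits = pwm_scan(window, fwd.reverse_complement(), p_threshold, scan_strand="-")
    by_offset: dict[int, MotifHit] = {}
    for h in hits + rc_hits:
        h = dataclasses.replace(h, motif="ypatch")
        prev = by_offset.get(h.start_offset)
        if prev is None or h.p_value < prev.p_value:
            by_offset[h.start_offset] = h
    return [by_offset[o] for o in sorted(by_offset)]


def motif_position_profile(
    hits: Iterable[MotifHit],
    offset_range: tuple[int, int] = (-50, 50),
) -> tuple[dict[int, int], int | None]:
    """Histogram of hit start offsets over a cohort, plus the modal offset.

    Returns ``(histogram, mode)``; the mode is ``None`` (flagged undefined)
    when there are no hits.  Modal ties break toward the 5'-most offset.
    """
    lo, hi = offset_range
    offsets = [o for o in range(lo, hi + 1) if o != 0]
    hist = {o: 0 for o in offsets}
    for h in hits:
        if h.start_offset in hist:
            hist[h.start_offset] += 1
    if all(v == 0 for v in hist.values()):
        return hist, None
    mode = max(hist, key=lambda o: (hist[o], -o))
    return hist, mode


def dinucleotide_matrix(windows: Sequence[PromoterWindow]) -> pd.DataFrame:
    """Fraction of windows carrying each dinucleotide at each start offset.

    Rows are the 16 dinucleotides, columns the start offsets; each column
    sums to 1 over the windows without ambiguous bases at that column.
    """
    if not windows:
        raise ValueError("need at least one window")
    flank = windows[0].flank
    n_cols = 2 * flank  # dinucleotide start indices 0 .. 2*flank-1
    dinucs = [a + b for a in BASES for b in BASES]
    counts = np.zeros((16, n_cols))
    valid = np.zeros(n_cols)
    row_index = {d: i for i, d in enumerate(dinucs)}
    for w in windows:
        if w.flank != flank:
            raise ValueError("windows must share the same flank")
        for i in range(n_cols):
            d = w.seq[i : i + 2]
            if d in row_index:
                counts[row_index[d], i] += 1
                valid[i] += 1
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = np.where(valid > 0, counts / valid, 0.0)
    columns = [index_to_offset(i, flank) for i in range(n_cols)]
    return pd.DataFrame(freq, index=dinucs, columns=columns)


def base_frequency_matrix(windows: Sequence[PromoterWindow]) -> pd.DataFrame:
    """Per-offset base frequencies over a cohort (sequence-logo data)."""
    if not windows:
        raise ValueError("need at least one window")
    flank = windows[0].flank
    n_cols = 2 * flank + 1
    counts = np.zeros((4, n_cols))
    valid = np.zeros(n_cols)
    for w in windows:
        for i, base in enumerate(w.seq):
            b = _BASE_INDEX.get(base)
            if b is not None:
                counts[b, i] += 1
                valid[i] += 1
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = np.where(valid > 0, counts / valid, 0.0)
    columns = [index_to_offset(i, flank) for i in range(n_cols)]
    return pd.DataFrame(freq, index=list(BASES), columns=columns)


@dataclasses.dataclass
class ArchitectureLabel:
    """Rule-based promoter architecture call for one cluster."""

    cluster_id: str
    tata: bool
    initiator: str
    ypatch: bool

    @property
    def label(self) -> str:
        parts = [("TATA+" if self.tata else "TATA-"), self.initiator]
        if self.ypatch:
            parts.append("Ypatch+")
        return "/".join(parts)


def classify_architecture(
    window: PromoterWindow,
    tata_hits: Sequence[MotifHit],
    ypatch_hits: Sequence[MotifHit],
    tata_offset_range: tuple[int, int] = (-40, -20),
) -> ArchitectureLabel:
    """Combine motif scans into an architecture label.

    The promoter is TATA+ iff any TATA hit starts within
    ``tata_offset_range`` (default -40..-20, bracketing the observed
    -36..-29 positional band); the initiator class comes from the (-1, +1)
    dinucleotide; Y-patch status is the presence of any Y-patch hit.
    """
    lo, hi = tata_offset_range
    tata = any(lo <= h.start_offset <= hi for h in tata_hits)
    inr, _ = initiator_class(window)
    return ArchitectureLabel(
        cluster_id=window.cluster_id,
        tata=tata,
        initiator=inr,
        ypatch=len(ypatch_hits) > 0,
    )


def te_overlap_fraction(
    dominant_positions: Sequence[tuple[str, int]],
    te_intervals: Sequence[IntervalRecord],
    flank: int = 50,
    groups: Sequence[str] | None = None,
) -> dict[str, float] | float:
    """Fraction of promoters whose +/-``flank`` bp TSS window intersects a
    transposable-element interval by >= 1 bp.

    With ``groups`` (one label per position, e.g. architecture classes),
    returns a per-group fraction dict; otherwise a single fraction.
    """
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom in {t.chrom for t in te_intervals}:
        ivs = sorted(
            ((t.start, t.end) for t in te_intervals if t.chrom == chrom)
        )
        starts = np.array([s for s, _ in ivs], dtype=np.int64)
        ends = np.array([e for _, e in ivs], dtype=np.int64)
        running_max_end = np.maximum.accumulate(ends) if len(ends) else ends
        by_chrom[chrom] = (starts, running_max_end)

    def _overlaps(chrom: str, pos: int) -> bool:
        if chrom not in by_chrom:
            return False
        starts, max_ends = by_chrom[chrom]
        i = int(np.searchsorted(starts, pos + flank, side="right"))
        if i == 0:
            return False
        return bool(max_ends[i - 1] >= pos - flank)

    flags = [_overlaps(chrom, pos) for chrom, pos in dominant_positions]
    if groups is None:
        return float(np.mean(flags)) if flags else 0.0
    out: dict[str, list[bool]] = {}
    for g, f in zip(groups, flags):
        out.setdefault(g, []).append(f)
    return {g: float(np.mean(v)) for g, v in sorted(out.items())}
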