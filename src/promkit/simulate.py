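"""Synthetic genomes, gene models and CTSS tracks with planted promoters.

The generator emits a fully truth-tagged dataset so every pipeline stage can
be scored without external data.  Planted promoter classes:

* ``tata_sharp`` — TATA-box promoter: a consensus-family 8-mer (TATAWAWA)
  planted with start at offset -32, CA initiator, sharply focused
  initiation (sigma ~1.5 bp);
* ``broad`` — TATA-less promoter with CG/TG PyPu initiator and dispersed
  initiation (sigma ~20 bp);
* ``ypatch`` — broad promoter with the pyrimidine-rich element CTTCTTCCTC
  planted in the 5' region upstream of the TSS;
* ``top`` — promoter whose transcript starts with a cytosine followed by a
  pyrimidine tract (length 5-13), with >= 80% of initiation on the tract
  start (a 5'TOP candidate);
* ``intron_singleton`` — an ordinarily broad promoter plus a
  single-position high-TPM "recapping" spike at the splice-acceptor AG of
  the first intron-exon junction;
* ``shifted`` — two alternative promoters ~500 bp apart; promoter A
  dominates in the first stage, promoter B in later stages.

Tag counts are negative-binomial draws around class-specific discretized
Gaussian positional kernels, with sparse sub-threshold intergenic noise.
Each gene owns an integer-seeded RNG stream (spawned in gene order from the
root seed), so outputs are byte-identical across runs and platforms for a
fixed seed.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .io_formats import (
    CtssTable,
    GeneModel,
    GenomeSequence,
    IntervalRecord,
    write_bed6,
    write_ctss_bedgraph,
    write_fasta,
    write_gff3,
)
from .motifs import TATA_FAMILY, YPATCH_CONSENSUS

__all__ = [
    "ClassMixture",
    "SimulationConfig",
    "SimulatedDataset",
    "simulate_genome_and_genes",
    "simulate_ctss_counts",
    "simulate_dataset",
    "write_dataset",
    "write_truth_table",
    "read_truth_table",
]

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}

CLASS_NAMES = ("tata_sharp", "broad", "ypatch", "top", "intron_singleton", "shifted")


@dataclasses.dataclass
class ClassMixture:
    """Fractions of promoter classes among simulated genes (sum <= 1;
    any remainder is assigned to ``broad``)."""

    tata_sharp: float = 0.2
    broad: float = 0.4
    ypatch: float = 0.1
    top: float = 0.1
    intron_singleton: float = 0.1
    shifted: float = 0.1

    def probabilities(self) -> np.ndarray:
        p = np.array(
            [getattr(self, name) for name in CLASS_NAMES], dtype=float
        )
        if np.any(p < 0) or p.sum() > 1 + 1e-9:
            raise ValueError("class fractions must be >= 0 and sum to <= 1")
        p[CLASS_NAMES.index("broad")] += max(0.0, 1.0 - p.sum())
        return p / p.sum()


@dataclasses.dataclass
class SimulationConfig:
    """Study conditions for the synthetic promoterome."""

    seed: int = 0
    n_genes: int = 500
    chrom_name: str = "chr1"
    gene_spacing: int = 5000
    margin: int = 5000
    gc: float = 0.45
    mixture: ClassMixture = dataclasses.field(default_factory=ClassMixture)
    stages: tuple[str, ...] = ("stage1", "stage2", "stage3")
    replicates: int = 2
    library_size: int = 1_000_000
    nb_size: float = 10.0  # negative-binomial dispersion (size parameter)
    sharp_sigma: float = 1.5
    broad_sigma: float = 20.0
    top_major_frac: float = 0.85  # initiation mass planted on the tract start
    shift_distance: int = 500
    shift_jitter: int = 20
    n_noise_positions: int = 200
    noise_min_spacing: int = 25
    plant_te: bool = True
    chrom_length: int = 0  # 0 = derived from n_genes and spacing

    def __post_init__(self) -> None:
        if self.chrom_length == 0:
            self.chrom_length = 2 * self.margin + self.n_genes * self.gene_spacing
        needed = 2 * self.margin + self.n_genes * self.gene_spacing
        if self.chrom_length < needed:
            raise ValueError(
                f"chrom_length {self.chrom_length} too short for {self.n_genes} "
                f"genes at spacing {self.gene_spacing} (need >= {needed})"
            )
        if self.replicates < 1 or self.n_genes < 0:
            raise ValueError("replicates >= 1 and n_genes >= 0 required")


@dataclasses.dataclass
class SimulatedDataset:
    config: SimulationConfig
    genome: GenomeSequence
    genes: list[GeneModel]
    truth: pd.DataFrame
    tables: dict[tuple[str, int], CtssTable]
    te_intervals: list[IntervalRecord]


# ---------------------------------------------------------------------------
# genome + gene construction
# ---------------------------------------------------------------------------


class _Planter:
    """Mutable genome with transcribed-strand edits in TSS-local coordinates.

    Local coordinate t counts bases downstream of the TSS (t = 0 is the TSS
    base, t = -1 the base just upstream); genomic position is
    ``tss + t`` on '+' and ``tss - t`` on '-', and planted bases are
    complemented on '-'.
    """

    def __init__(self, arr: np.ndarray):
        self.arr = arr  # 1-byte chars, 0-based genomic index

    def set_local(self, tss: int, strand: str, t: int, base: str) -> None:
        if strand == "+":
            self.arr[tss + t - 1] = base.encode()
        else:
            self.arr[tss - t - 1] = _COMP[base].encode()

    def get_local(self, tss: int, strand: str, t: int) -> str:
        if strand == "+":
            return self.arr[tss + t - 1].decode()
        return _COMP[self.arr[tss - t - 1].decode()]

    def plant(self, tss: int, strand: str, t_start: int, seq: str) -> None:
        for i, base in enumerate(seq):
            self.set_local(tss, strand, t_start + i, base)

    def read_local(self, tss: int, strand: str, t_start: int, length: int) -> str:
        return "".join(
            self.get_local(tss, strand, t_start + i) for i in range(length)
        )


_TATA_SET = frozenset(TATA_FAMILY)


def _scrub_tata(planter: _Planter, tss: int, strand: str) -> None:
    """Destroy accidental TATA-family 8-mers starting in offsets -40..-20."""
    for t in range(-40, -19):
        if planter.read_local(tss, strand, t, 8) in _TATA_SET:
            planter.set_local(tss, strand, t + 2, "G")


def _gene_layout(cls: str, rng: np.random.Generator, cfg: SimulationConfig):
    """Transcript-local exon/CDS layout and class-specific plant positions."""
    if cls == "shifted":
        t_b = int(cfg.shift_distance + rng.integers(-cfg.shift_jitter, cfg.shift_jitter + 1))
        exons = [(0, 699), (1200, 1799)]
        if rng.random() < 0.5:
            # CDS starts between promoter A and promoter B -> coding shift
            cds = [(350, 699), (1200, 1599)]
            consequence = "coding"
        else:
            cds = [(620, 699), (1200, 1599)]
            consequence = "utr5_promoter"
        return exons, cds, {"t_b": t_b, "consequence": consequence}
    exons = [(0, 299), (800, 1399)]
    cds = [(150, 299), (800, 1199)]
    return exons, cds, {}


def simulate_genome_and_genes(
    config: SimulationConfig,
) -> tuple[GenomeSequence, list[GeneModel], pd.DataFrame, list[IntervalRecord]]:
    """Generate the background genome, gene models, planted promoter
    sequences, optional TE intervals and the truth-table skeleton."""
    root = np.random.SeedSequence(config.seed)
    genome_ss, genes_ss, te_ss = root.spawn(3)
    rng_genome = np.random.default_rng(genome_ss)
    p = np.array(
        [(1 - config.gc) / 2, config.gc / 2, config.gc / 2, (1 - config.gc) / 2]
    )
    arr = rng_genome.choice(np.frombuffer(b"ACGT", dtype="S1"), size=config.chrom_length, p=p)
    planter = _Planter(arr)

    probs = config.mixture.probabilities()
    gene_streams = genes_ss.spawn(max(config.n_genes, 1))
    genes: list[GeneModel] = []
    truth_rows: list[dict] = []
    te_records: list[IntervalRecord] = []
    rng_te = np.random.default_rng(te_ss)

    for i in range(config.n_genes):
        rng = np.random.default_rng(gene_streams[i])
        cls = CLASS_NAMES[int(rng.choice(len(CLASS_NAMES), p=probs))]
        strand = "+" if rng.random() < 0.5 else "-"
        block = config.margin + i * config.gene_spacing
        jitter = int(rng.integers(0, 200))
        exons_t, cds_t, extra = _gene_layout(cls, rng, config)
        gene_len = exons_t[-1][1] + 1
        if strand == "+":
            tss = block + 1200 + jitter
            to_genomic = lambda a, b: (tss + a, tss + b)
        else:
            tss = block + 1200 + jitter + gene_len - 1
            to_genomic = lambda a, b: (tss - b, tss - a)
        exons = sorted(to_genomic(a, b) for a, b in exons_t)
        cds = sorted(to_genomic(a, b) for a, b in cds_t)

        # --- plant the promoter sequence on the transcribed strand ---
        row: dict = {
            "gene_id": f"G{i + 1:04d}",
            "class": cls,
            "chrom": config.chrom_name,
            "strand": strand,
            "aTSS": tss,
            "tata_offset": np.nan,
            "initiator": "",
            "ypatch_offset": np.nan,
            "top_tract_len": 0,
            "singleton_pos": np.nan,
            "shift": cls == "shifted",
            "shift_pos_b": np.nan,
            "shift_distance": np.nan,
            "shift_consequence": "",
        }

        if cls == "tata_sharp":
            member = TATA_FAMILY[int(rng.integers(len(TATA_FAMILY)))]
            planter.plant(tss, strand, -32, member)
            planter.set_local(tss, strand, -1, "C")
            planter.set_local(tss, strand, 0, "A")
            row["tata_offset"] = -32
            row["initiator"] = "CA"
        else:
            _scrub_tata(planter, tss, strand)
            if cls == "top":
                tract_len = int(rng.integers(5, 14))
                tract = "C" + "".join(
                    rng.choice(["C", "T"]) for _ in range(tract_len - 1)
                )
                planter.plant(tss, strand, 0, tract)
                planter.set_local(tss, strand, tract_len, "A")  # terminate run
                planter.set_local(tss, strand, -1, "T")
                row["top_tract_len"] = tract_len
                row["initiator"] = "TC"
            else:
                inr = "CG" if rng.random() < 0.5 else "TG"
                if cls == "ypatch":
                    off = int(rng.integers(-30, -9))  # start offset in [-30, -10]
                    planter.plant(tss, strand, off, YPATCH_CONSENSUS)
                    row["ypatch_offset"] = off
                planter.set_local(tss, strand, -1, inr[0])
                planter.set_local(tss, strand, 0, inr[1])
                row["initiator"] = inr

        if cls == "intron_singleton":
            # splice-acceptor CAG at the first intron/exon-2 junction;
            # the recapping spike sits on the acceptor G (last intron base)
            planter.plant(tss, strand, 797, "CAG")
            row["singleton_pos"] = tss + 799 if strand == "+" else tss - 799

        if cls == "shifted":
            t_b = extra["t_b"]
            for t_center in (0, t_b):
                _scrub_tata_at(planter, tss, strand, t_center)
            planter.set_local(tss, strand, -1, "C")
            planter.set_local(tss, strand, 0, "G")
            planter.set_local(tss, strand, t_b - 1, "C")
            planter.set_local(tss, strand, t_b, "G")
            row["initiator"] = "CG"
            pos_b = tss + t_b if strand == "+" else tss - t_b
            row["shift_pos_b"] = pos_b
            row["shift_distance"] = abs(pos_b - tss)
            row["shift_consequence"] = extra["consequence"]

        # per-gene expression jitter, drawn here so count simulation only
        # consumes the per-gene count streams
        row["expr_jitter"] = float(np.exp(rng.normal(0.0, 0.4)))
        for s in config.stages:
            row[f"dom_{s}"] = tss
        if cls == "shifted":
            for s in config.stages[1:]:
                row[f"dom_{s}"] = row["shift_pos_b"]

        genes.append(
            GeneModel(
                gene_id=row["gene_id"],
                chrom=config.chrom_name,
                strand=strand,
                exons=exons,
                cds=cds,
                confidence="high" if rng.random() < 0.9 else "low",
            )
        )
        truth_rows.append(row)

        if config.plant_te and cls in ("broad", "ypatch") and rng.random() < 0.12:
            if strand == "+":
                te_records.append(
                    IntervalRecord(config.chrom_name, tss - 120, tss - 30, strand=".", name="TE")
                )
            else:
                te_records.append(
                    IntervalRecord(config.chrom_name, tss + 30, tss + 120, strand=".", name="TE")
                )

    # a handful of intergenic TEs far from any promoter
    if config.plant_te and config.n_genes:
        for _ in range(20):
            i = int(rng_te.integers(config.n_genes))
            block = config.margin + i * config.gene_spacing
            start = block + 4000 + int(rng_te.integers(0, 400))
            te_records.append(
                IntervalRecord(config.chrom_name, start, start + 200, strand=".", name="TE_intergenic")
            )
    te_records.sort(key=lambda r: (r.chrom, r.start))

    genome = GenomeSequence({config.chrom_name: arr.tobytes().decode("ascii")})
    truth = pd.DataFrame(truth_rows)
    return genome, genes, truth, te_records


def _scrub_tata_at(planter: _Planter, tss: int, strand: str, t_center: int) -> None:
    for t in range(t_center - 40, t_center - 19):
        if planter.read_local(tss, strand, t, 8) in _TATA_SET:
            planter.set_local(tss, strand, t + 2, "G")


# ---------------------------------------------------------------------------
# count simulation
# ---------------------------------------------------------------------------


def _gaussian_kernel(sigma: float, max_half_width: int = 60) -> np.ndarray:
    """Discretized, truncated Gaussian positional kernel (sums to 1)."""
    k = min(int(np.ceil(4 * sigma)), max_half_width)
    d = np.arange(-k, k + 1, dtype=float)
    w = np.exp(-0.5 * (d / sigma) ** 2)
    return w / w.sum()


@dataclasses.dataclass
class _EmissionUnit:
    gene_index: int
    positions: np.ndarray  # genomic positions, ascending
    kernel: np.ndarray  # same length, sums to 1
    weight: float
    stage_factors: np.ndarray  # one factor per stage


_CLASS_WEIGHT = {
    "tata_sharp": 3.0,
    "broad": 1.0,
    "ypatch": 1.0,
    "top": 2.0,
    "intron_singleton": 1.0,
    "shifted": 1.5,
}
_SINGLETON_WEIGHT = 0.5
_SHIFT_MINOR = 0.125  # off-stage activity of each alternative promoter


def _build_units(config: SimulationConfig, truth: pd.DataFrame) -> list[_EmissionUnit]:
    n_stages = len(config.stages)
    units: list[_EmissionUnit] = []
    for i, row in truth.iterrows():
        cls = row["class"]
        strand = row["strand"]
        tss = int(row["aTSS"])
        sign = 1 if strand == "+" else -1
        w = _CLASS_WEIGHT[cls] * row["expr_jitter"]

        if cls == "top":
            spread = _gaussian_kernel(2.0)
            k = (len(spread) - 1) // 2
            kernel = spread * (1 - config.top_major_frac)
            kernel[k] += config.top_major_frac
        elif cls in ("tata_sharp", "shifted"):
            kernel = _gaussian_kernel(config.sharp_sigma)
            k = (len(kernel) - 1) // 2
        else:
            kernel = _gaussian_kernel(config.broad_sigma)
            k = (len(kernel) - 1) // 2
        offs = np.arange(-k, k + 1)

        def _positions(center: int) -> np.ndarray:
            pos = center + sign * offs
            return pos

        if cls == "shifted":
            factors_a = np.full(n_stages, _SHIFT_MINOR)
            factors_a[0] = 1.0
            factors_b = np.full(n_stages, 1.0)
            factors_b[0] = _SHIFT_MINOR
            units.append(
                _EmissionUnit(i, _positions(tss), kernel, w, factors_a)
            )
            units.append(
                _EmissionUnit(i, _positions(int(row["shift_pos_b"])), kernel, w, factors_b)
            )
        else:
            units.append(
                _EmissionUnit(i, _positions(tss), kernel, w, np.ones(n_stages))
            )
        if cls == "intron_singleton":
            units.append(
                _EmissionUnit(
                    i,
                    np.array([int(row["singleton_pos"])]),
                    np.array([1.0]),
                    _SINGLETON_WEIGHT * row["expr_jitter"],
                    np.ones(n_stages),
                )
            )
    return units


def simulate_ctss_counts(
    config: SimulationConfig,
    truth: pd.DataFrame,
    genes: Sequence[GeneModel],
) -> dict[tuple[str, int], CtssTable]:
    """Draw per-stage, per-replicate CTSS tables around the planted TSSs.

    Per stage, expected per-unit totals are the class weights (times the
    per-gene jitter and stage factor) scaled so each replicate's expected
    signal equals ``library_size``; counts per position are negative
    binomial around the positional kernel.  Sparse intergenic noise
    singletons (count 1-2) are added per replicate.
    """
    root = np.random.SeedSequence(config.seed)
    _, _, _, counts_ss, noise_ss = root.spawn(5)
    units = _build_units(config, truth)
    n_stages = len(config.stages)

    # per-stage normalization so every stage's expected library is equal
    stage_weight_sum = np.zeros(n_stages)
    for u in units:
        stage_weight_sum += u.weight * u.stage_factors
    # per-stage scale; zero when there are no signal units (noise-only runs)
    scale = np.divide(
        float(config.library_size),
        stage_weight_sum,
        out=np.zeros_like(stage_weight_sum),
        where=stage_weight_sum > 0,
    )

    gene_streams = counts_ss.spawn(max(config.n_genes, 1))
    gene_rngs = [np.random.default_rng(s) for s in gene_streams]
    noise_streams = noise_ss.spawn(n_stages * config.replicates)

    # exclusion zones for noise placement
    occupied: list[tuple[int, int]] = sorted(
        (g.start - 1500, g.end + 1500) for g in genes
    )
    occ_starts = np.array([s for s, _ in occupied], dtype=np.int64)
    occ_ends = np.array([e for _, e in occupied], dtype=np.int64)

    tables: dict[tuple[str, int], CtssTable] = {}
    r = config.nb_size
    for s_idx, stage in enumerate(config.stages):
        for rep in range(1, config.replicates + 1):
            frames = []
            for u in units:
                rng = gene_rngs[u.gene_index]
                mu = u.weight * u.stage_factors[s_idx] * scale[s_idx]
                lam = mu * u.kernel
                counts = rng.negative_binomial(r, r / (r + lam))
                keep = counts > 0
                if not np.any(keep):
                    continue
                row = truth.iloc[u.gene_index]
                frames.append(
                    pd.DataFrame(
                        {
                            "chrom": row["chrom"],
                            "pos": u.positions[keep],
                            "strand": row["strand"],
                            "count": counts[keep],
                        }
                    )
                )
            nrng = np.random.default_rng(
                noise_streams[s_idx * config.replicates + (rep - 1)]
            )
            noise = _draw_noise(config, nrng, occ_starts, occ_ends)
            if len(noise):
                frames.append(noise)
            if not frames:
                frames.append(
                    pd.DataFrame(columns=["chrom", "pos", "strand", "count"])
                )
            df = pd.concat(frames, ignore_index=True)
            df = (
                df.groupby(["chrom", "pos", "strand"], as_index=False)["count"].sum()
            )
            tables[(stage, rep)] = CtssTable(df=df)
    return tables


def _draw_noise(
    config: SimulationConfig,
    rng: np.random.Generator,
    occ_starts: np.ndarray,
    occ_ends: np.ndarray,
) -> pd.DataFrame:
    """Sparse intergenic noise: single positions, pairwise well separated."""
    chosen: list[int] = []
    attempts = 0
    max_attempts = config.n_noise_positions * 50
    while len(chosen) < config.n_noise_positions and attempts < max_attempts:
        attempts += 1
        pos = int(rng.integers(1, config.chrom_length + 1))
        j = int(np.searchsorted(occ_starts, pos, side="right"))
        if j > 0 and occ_ends[j - 1] >= pos:
            continue
        if any(abs(pos - c) < config.noise_min_spacing for c in chosen):
            continue
        chosen.append(pos)
    if not chosen:
        return pd.DataFrame(columns=["chrom", "pos", "strand", "count"])
    chosen.sort()
    strands = np.where(rng.random(len(chosen)) < 0.5, "+", "-")
    counts = 1 + (rng.random(len(chosen)) < 0.15).astype(int)
    return pd.DataFrame(
        {
            "chrom": config.chrom_name,
            "pos": np.array(chosen, dtype=np.int64),
            "strand": strands,
            "count": counts,
        }
    )


def simulate_dataset(config: SimulationConfig) -> SimulatedDataset:
    """Full simulation: genome, genes, truth table and CTSS tables."""
    genome, genes, truth, te = simulate_genome_and_genes(config)
    tables = simulate_ctss_counts(config, truth, genes)
    return SimulatedDataset(
        config=config, genome=genome, genes=genes, truth=truth,
        tables=tables, te_intervals=te,
    )


# ---------------------------------------------------------------------------
# on-disk dataset
# ---------------------------------------------------------------------------

TRUTH_FILE = "truth.tsv"


def write_truth_table(truth: pd.DataFrame, path: str | Path) -> None:
    truth.to_csv(path, sep="\t", index=False)


def read_truth_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"chrom": str, "initiator": str})


def write_dataset(dataset: SimulatedDataset, outdir: str | Path) -> None:
    """Emit FASTA, GFF3, per-sample bedGraph pairs, TE BED and truth TSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_fasta(dataset.genome, outdir / "genome.fasta")
    write_gff3(dataset.genes, outdir / "genes.gff3")
    write_truth_table(dataset.truth, outdir / TRUTH_FILE)
    write_bed6(dataset.te_intervals, outdir / "te.bed")
    for (stage, rep), table in sorted(dataset.tables.items()):
        stem = f"ctss_{stage}_rep{rep}"
        write_ctss_bedgraph(
            table, outdir / f"{stem}_plus.bedGraph", outdir / f"{stem}_minus.bedGraph"
        )
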