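"""End-to-end orchestration: CTSS tracks -> annotated promoter catalog.

The pipeline runs as a sequence of file-based stages inside one working
directory (cluster -> consensus -> annotate -> features -> topscore -> tau
-> shifts -> report); every stage reads the TSV intermediates written by
its predecessors, so any stage can be re-run in isolation and produces the
same output as a full run.  All thresholds live in :class:`PipelineConfig`
and are echoed into the run log and summary.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import annotation as ann_mod
from . import clustering as clu
from . import motifs as mot
from . import shifts as shf
from . import topspec as tps
from .io_formats import (
    CtssTable,
    GeneModel,
    GenomeSequence,
    read_bed6,
    read_ctss_bedgraph,
    read_ctss_4col,
    read_fasta,
    read_gff3,
    write_catalog,
)

logger = logging.getLogger("promkit")

__all__ = [
    "SampleSpec",
    "PipelineConfig",
    "discover_samples",
    "stage_cluster",
    "stage_consensus",
    "stage_annotate",
    "stage_features",
    "stage_topscore",
    "stage_tau",
    "stage_shifts",
    "stage_report",
    "run_pipeline",
    "STAGE_ORDER",
]


@dataclasses.dataclass
class SampleSpec:
    """One CTSS input sample: a stage/replicate with its track files."""

    stage: str
    replicate: int
    plus: str = ""
    minus: str = ""
    ctss4: str = ""

    def load(self) -> CtssTable:
        if self.ctss4:
            return read_ctss_4col(self.ctss4)
        return read_ctss_bedgraph(self.plus, self.minus)


@dataclasses.dataclass
class PipelineConfig:
    """All inputs and thresholds of a pipeline run."""

    genome_fasta: str
    gff3: str
    samples: list[SampleSpec]
    workdir: str
    te_bed: str = ""
    expression_matrix: str = ""  # optional external genes x tissues TSV
    tata_pwm: str = ""  # optional JASPAR/MEME file; default = shipped matrix

    # clustering / filtering
    ctss_max_dist: int = 20
    consensus_max_gap: int = 100
    tpm_min: float = 0.1
    singleton_tpm_min: float = 5.0
    replicate_min_fraction: float = 0.9
    q_low: float = 0.1
    q_up: float = 0.9
    # annotation
    promoter_window: tuple[int, int] = (-500, 100)
    proximal_window: tuple[int, int] = (-1000, -501)
    unassociated_cutoff: int = 1000
    concordance_thresholds: tuple[int, ...] = (20, 100, 500)
    # core-promoter features
    flank: int = 50
    pwm_p: float = 1e-4
    pwm_p_lenient: float = 1e-3
    ypatch_p: float = 1e-4
    tata_offset_range: tuple[int, int] = (-40, -20)
    # TOP / tau
    top_threshold: float = 3.0
    tau_transform: str = "log2p1"
    # shifts
    shift_min_tpm: float = 0.5
    shift_min_fold: float = 2.0

    seed: int = 0

    @property
    def stages(self) -> list[str]:
        seen: list[str] = []
        for s in self.samples:
            if s.stage not in seen:
                seen.append(s.stage)
        return seen

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        samples = [SampleSpec(**s) for s in raw.pop("samples")]
        for key in ("promoter_window", "proximal_window", "tata_offset_range",
                    "concordance_thresholds"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(samples=samples, **raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


def discover_samples(data_dir: str | Path) -> list[SampleSpec]:
    """Find bedGraph sample pairs named ``ctss_<stage>_rep<k>_plus/minus``."""
    data_dir = Path(data_dir)
    specs = []
    for plus in sorted(data_dir.glob("ctss_*_rep*_plus.bedGraph")):
        stem = plus.name[len("ctss_") : -len("_plus.bedGraph")]
        stage, rep = stem.rsplit("_rep", 1)
        minus = plus.with_name(plus.name.replace("_plus.", "_minus."))
        specs.append(
            SampleSpec(stage=stage, replicate=int(rep), plus=str(plus), minus=str(minus))
        )
    if not specs:
        raise FileNotFoundError(f"no CTSS bedGraph pairs found in {data_dir}")
    specs.sort(key=lambda s: (s.stage, s.replicate))
    return specs


# ---------------------------------------------------------------------------
# stage implementations
# ---------------------------------------------------------------------------


def _wd(config: PipelineConfig) -> Path:
    wd = Path(config.workdir)
    wd.mkdir(parents=True, exist_ok=True)
    return wd


def _tc_path(wd: Path, stage: str) -> Path:
    return wd / f"tc_{stage}.tsv"


def _pooled_path(wd: Path, stage: str) -> Path:
    return wd / f"pooled_ctss_{stage}.tsv"


def stage_cluster(config: PipelineConfig) -> None:
    """Per stage: cluster each replicate, keep replicate-consistent regions,
    pool replicate counts, re-cluster, quantify and apply the TPM filters."""
    wd = _wd(config)
    (wd / "config_echo.yaml").write_text(yaml.safe_dump(config.to_dict(), sort_keys=True))
    by_stage: dict[str, list[SampleSpec]] = {}
    for s in config.samples:
        by_stage.setdefault(s.stage, []).append(s)
    libraries: dict[str, int] = {}
    stage_counts: dict[str, dict] = {}
    for stage in config.stages:
        reps = sorted(by_stage[stage], key=lambda s: s.replicate)
        tables = [spec.load() for spec in reps]
        rep_regions = []
        for table in tables:
            tcs = clu.cluster_and_quantify(
                table, max_dist=config.ctss_max_dist,
                q_low=config.q_low, q_up=config.q_up,
            )
            regions: dict[tuple[str, str], list[tuple[int, int]]] = {}
            for tc in tcs:
                regions.setdefault((tc.chrom, tc.strand), []).append((tc.start, tc.end))
            rep_regions.append(regions)
        # fold the reciprocal 90%-coverage filter over replicates
        kept = rep_regions[0]
        for other in rep_regions[1:]:
            merged: dict[tuple[str, str], list[tuple[int, int]]] = {}
            for key in sorted(set(kept) | set(other)):
                merged[key] = clu.replicate_consistency_filter(
                    kept.get(key, []), other.get(key, []),
                    min_fraction=config.replicate_min_fraction,
                )
            kept = merged
        pooled = CtssTable.pool(tables)
        mask = np.zeros(len(pooled.df), dtype=bool)
        for (chrom, strand), regions in kept.items():
            if not regions:
                continue
            sub = (pooled.df["chrom"] == chrom) & (pooled.df["strand"] == strand)
            pos = pooled.df["pos"].to_numpy()
            starts = np.array([r[0] for r in regions])
            ends = np.array([r[1] for r in regions])
            idx = np.searchsorted(starts, pos, side="right") - 1
            inside = (idx >= 0) & (pos <= ends[np.clip(idx, 0, len(ends) - 1)])
            mask |= sub.to_numpy() & inside
        kept_df = pooled.df[mask].reset_index(drop=True)
        kept_table = CtssTable(df=kept_df, library_size=pooled.library_size) if len(kept_df) else None
        if kept_table is None:
            tcs_all: list[clu.TagCluster] = []
        else:
            tcs_all = clu.cluster_and_quantify(
                kept_table, sample=stage, max_dist=config.ctss_max_dist,
                q_low=config.q_low, q_up=config.q_up,
            )
        tcs_filtered = clu.filter_clusters(
            tcs_all, tpm_min=config.tpm_min,
            singleton_tpm_min=config.singleton_tpm_min,
        )
        stage_counts[stage] = {
            "ctss_positions_pooled": int(len(pooled.df)),
            "ctss_positions_replicated": int(len(kept_df)),
            "tag_clusters_raw": len(tcs_all),
            "tag_clusters_filtered": len(tcs_filtered),
        }
        logger.info(
            "stage %s: %d TCs raw, %d after TPM filters", stage,
            len(tcs_all), len(tcs_filtered),
        )
        clu.tag_clusters_to_frame(tcs_filtered).to_csv(
            _tc_path(wd, stage), sep="\t", index=False
        )
        pooled_out = kept_df if kept_table is not None else pooled.df.iloc[:0]
        pooled_out.to_csv(_pooled_path(wd, stage), sep="\t", index=False)
        libraries[stage] = pooled.library_size
    (wd / "libraries.json").write_text(json.dumps(libraries, indent=2, sort_keys=True))
    (wd / "cluster_counts.json").write_text(
        json.dumps(stage_counts, indent=2, sort_keys=True)
    )


def _load_stage_tcs(config: PipelineConfig) -> dict[str, list[clu.TagCluster]]:
    """Rebuild TagCluster objects (with member CTSSs) from intermediates."""
    wd = _wd(config)
    libraries = json.loads((wd / "libraries.json").read_text())
    out: dict[str, list[clu.TagCluster]] = {}
    for stage in config.stages:
        tc_df = pd.read_csv(_tc_path(wd, stage), sep="\t", dtype={"chrom": str})
        pooled = pd.read_csv(_pooled_path(wd, stage), sep="\t", dtype={"chrom": str})
        tcs = []
        for row in tc_df.itertuples():
            sub = pooled[
                (pooled["chrom"] == row.chrom)
                & (pooled["strand"] == row.strand)
                & (pooled["pos"] >= row.start)
                & (pooled["pos"] <= row.end)
            ]
            tcs.append(
                clu.quantify_cluster(
                    sub["pos"].to_numpy(), sub["count"].to_numpy(),
                    strand=row.strand, chrom=row.chrom, sample=stage,
                    library_size=libraries[stage],
                    q_low=config.q_low, q_up=config.q_up,
                )
            )
        out[stage] = tcs
    return out


def stage_consensus(config: PipelineConfig) -> None:
    """Merge per-stage TCs into consensus clusters (single linkage,
    gap < ``consensus_max_gap``)."""
    wd = _wd(config)
    tcs = _load_stage_tcs(config)
    consensus = clu.aggregate_consensus(
        tcs, max_gap=config.consensus_max_gap,
        q_low=config.q_low, q_up=config.q_up,
    )
    rows = []
    for c in consensus:
        row = {
            "cluster_id": c.cluster_id,
            "chrom": c.chrom,
            "strand": c.strand,
            "start": c.start,
            "end": c.end,
            "dominant_pos": c.dominant_pos,
            "dominant_stage": c.dominant_stage,
            "iqw": c.iqw,
        }
        for stage in config.stages:
            row[f"tpm_{stage}"] = c.tpm.get(stage, 0.0)
            dp = c.stage_dominant_pos.get(stage)
            row[f"dominant_pos_{stage}"] = -1 if dp is None else dp
        rows.append(row)
    cols = ["cluster_id", "chrom", "strand", "start", "end", "dominant_pos",
            "dominant_stage", "iqw"]
    for stage in config.stages:
        cols += [f"tpm_{stage}", f"dominant_pos_{stage}"]
    pd.DataFrame(rows, columns=cols).to_csv(wd / "consensus.tsv", sep="\t", index=False)
    logger.info("%d consensus clusters", len(rows))


def _load_consensus(config: PipelineConfig) -> list[clu.ConsensusCluster]:
    wd = _wd(config)
    df = pd.read_csv(wd / "consensus.tsv", sep="\t", dtype={"chrom": str})
    clusters = []
    for row in df.itertuples():
        tpm = {s: float(getattr(row, f"tpm_{s}")) for s in config.stages}
        sdp = {
            s: int(getattr(row, f"dominant_pos_{s}"))
            for s in config.stages
            if int(getattr(row, f"dominant_pos_{s}")) >= 0
        }
        clusters.append(
            clu.ConsensusCluster(
                chrom=row.chrom, strand=row.strand, start=int(row.start),
                end=int(row.end), members={}, tpm=tpm, stage_dominant_pos=sdp,
                dominant_pos=int(row.dominant_pos),
                dominant_stage=row.dominant_stage, iqw=int(row.iqw),
                cluster_id=row.cluster_id,
            )
        )
    return clusters


def stage_annotate(config: PipelineConfig) -> None:
    """Feature categories, gene assignment and the primary/secondary split."""
    wd = _wd(config)
    clusters = _load_consensus(config)
    genes = read_gff3(config.gff3)
    annotations = ann_mod.annotate_clusters(
        clusters, genes,
        promoter_window=config.promoter_window,
        proximal_window=config.proximal_window,
        unassociated_cutoff=config.unassociated_cutoff,
    )
    assignments, secondary = ann_mod.split_primary_secondary(annotations)
    primary_ids = {a.primary for a in assignments}
    rows = []
    for c, a in zip(clusters, annotations):
        rows.append(
            {
                "cluster_id": c.cluster_id,
                "gene_id": a.gene_id if a.gene_id is not None else "",
                "category": a.category,
                "signed_distance": (
                    a.signed_distance if a.signed_distance is not None else np.nan
                ),
                "orientation": a.orientation if a.orientation else "",
                "is_primary": c.cluster_id in primary_ids,
            }
        )
    ann_cols = ["cluster_id", "gene_id", "category", "signed_distance",
                "orientation", "is_primary"]
    pd.DataFrame(rows, columns=ann_cols).to_csv(wd / "annotated.tsv", sep="\t", index=False)
    logger.info(
        "%d primary promoters, %d secondary clusters", len(assignments), len(secondary)
    )


def _tata_matrix(config: PipelineConfig) -> mot.PositionWeightMatrix:
    if config.tata_pwm:
        return mot.load_pwm(config.tata_pwm)
    return mot.default_tata_pwm()


def stage_features(config: PipelineConfig) -> None:
    """Promoter windows, initiator class, TATA / Y-patch scans,
    architecture labels, positional profile and dinucleotide matrices."""
    wd = _wd(config)
    clusters = _load_consensus(config)
    genome = read_fasta(config.genome_fasta)
    tata = _tata_matrix(config)
    rows = []
    windows: list[mot.PromoterWindow] = []
    all_tata_hits: list[mot.MotifHit] = []
    skipped = 0
    for c in clusters:
        window = mot.extract_window(
            genome, c.chrom, c.dominant_pos, c.strand,
            flank=config.flank, cluster_id=c.cluster_id,
        )
        if window is None:
            skipped += 1
            logger.warning("cluster %s window crosses contig edge; skipped", c.cluster_id)
            rows.append(
                {
                    "cluster_id": c.cluster_id,
                    "initiator": "NA",
                    "initiator_ambiguous": True,
                    "tata": False,
                    "tata_lenient": False,
                    "tata_offset": np.nan,
                    "ypatch": False,
                    "architecture": "NA",
                    "window_ok": False,
                }
            )
            continue
        windows.append(window)
        tata_hits = mot.pwm_scan(window, tata, config.pwm_p)
        tata_hits_lenient = mot.pwm_scan(window, tata, config.pwm_p_lenient)
        yp_hits = mot.ypatch_scan(window, config.ypatch_p)
        arch = mot.classify_architecture(
            window, tata_hits, yp_hits, tata_offset_range=config.tata_offset_range
        )
        lo, hi = config.tata_offset_range
        all_tata_hits.extend(h for h in tata_hits if lo <= h.start_offset <= hi)
        inr, ambiguous = mot.initiator_class(window)
        rows.append(
            {
                "cluster_id": c.cluster_id,
                "initiator": inr,
                "initiator_ambiguous": ambiguous,
                "tata": arch.tata,
                "tata_lenient": any(
                    lo <= h.start_offset <= hi for h in tata_hits_lenient
                ),
                "tata_offset": (
                    min(
                        (h.start_offset for h in tata_hits if lo <= h.start_offset <= hi),
                        default=np.nan,
                    )
                ),
                "ypatch": arch.ypatch,
                "architecture": arch.label,
                "window_ok": True,
            }
        )
    feature_cols = [
        "cluster_id", "initiator", "initiator_ambiguous", "tata",
        "tata_lenient", "tata_offset", "ypatch", "architecture", "window_ok",
    ]
    pd.DataFrame(rows, columns=feature_cols).to_csv(
        wd / "features.tsv", sep="\t", index=False
    )
    hist, mode = mot.motif_position_profile(all_tata_hits, offset_range=(-config.flank, config.flank))
    prof = pd.DataFrame(
        {"offset": list(hist.keys()), "tata_hits": list(hist.values())}
    )
    prof.to_csv(wd / "tata_position_profile.tsv", sep="\t", index=False)
    if windows:
        mot.dinucleotide_matrix(windows).to_csv(wd / "dinucleotide_matrix.tsv", sep="\t")
        mot.base_frequency_matrix(windows).to_csv(wd / "base_frequencies.tsv", sep="\t")
    meta = {"tata_positional_mode": mode, "windows_skipped_at_contig_edge": skipped}
    (wd / "features_meta.json").write_text(json.dumps(meta, indent=2, sort_keys=True))
    logger.info("features computed for %d windows (%d skipped)", len(windows), skipped)


def stage_topscore(config: PipelineConfig) -> None:
    """Gene-level TOPscore over the primary cluster's CTSSs (all stages)."""
    wd = _wd(config)
    genome = read_fasta(config.genome_fasta)
    annotated = pd.read_csv(wd / "annotated.tsv", sep="\t", dtype={"gene_id": str})
    consensus = pd.read_csv(wd / "consensus.tsv", sep="\t", dtype={"chrom": str})
    merged = annotated.merge(consensus, on="cluster_id")
    pooled_frames = [
        pd.read_csv(_pooled_path(wd, stage), sep="\t", dtype={"chrom": str})
        for stage in config.stages
    ]
    pooled = (
        pd.concat(pooled_frames, ignore_index=True)
        .groupby(["chrom", "pos", "strand"], as_index=False)["count"]
        .sum()
        if pooled_frames
        else pd.DataFrame(columns=["chrom", "pos", "strand", "count"])
    )
    rows = []
    primaries = merged[merged["is_primary"].astype(bool)]
    for row in primaries.itertuples():
        sub = pooled[
            (pooled["chrom"] == row.chrom)
            & (pooled["strand"] == row.strand)
            & (pooled["pos"] >= row.start)
            & (pooled["pos"] <= row.end)
        ]
        if not len(sub):
            continue
        ctss = [
            (r.chrom, int(r.pos), r.strand, int(r.count)) for r in sub.itertuples()
        ]
        rec = tps.gene_topscore(row.gene_id, ctss, genome)
        rows.append(
            {
                "gene_id": row.gene_id,
                "cluster_id": row.cluster_id,
                "topscore": rec.topscore,
                "is_top_candidate": rec.topscore > config.top_threshold,
            }
        )
    out = pd.DataFrame(
        rows, columns=["gene_id", "cluster_id", "topscore", "is_top_candidate"]
    )
    out.to_csv(wd / "topscore.tsv", sep="\t", index=False)
    logger.info("TOPscore computed for %d genes", len(rows))


def stage_tau(config: PipelineConfig) -> None:
    """tau per gene, from an external expression matrix when provided,
    otherwise from the primary cluster's per-stage TPMs."""
    wd = _wd(config)
    if config.expression_matrix:
        matrix = pd.read_csv(config.expression_matrix, sep="\t", index_col=0)
    else:
        annotated = pd.read_csv(wd / "annotated.tsv", sep="\t", dtype={"gene_id": str})
        consensus = pd.read_csv(wd / "consensus.tsv", sep="\t", dtype={"chrom": str})
        merged = annotated.merge(consensus, on="cluster_id")
        primaries = merged[merged["is_primary"].astype(bool)].set_index("gene_id")
        matrix = primaries[[f"tpm_{s}" for s in config.stages]]
        matrix.columns = list(config.stages)
    table = tps.tau_table(matrix, transform=config.tau_transform)
    if not len(table):
        table = pd.DataFrame(columns=["gene_id", "tau", "n_tissues", "max_tissue"])
    table.to_csv(wd / "tau.tsv", sep="\t", index=False)
    logger.info("tau computed for %d genes", len(table))


def stage_shifts(config: PipelineConfig) -> None:
    """Promoter-shift calls for every ordered stage pair, with consequences."""
    wd = _wd(config)
    clusters = _load_consensus(config)
    annotated = pd.read_csv(wd / "annotated.tsv", sep="\t", dtype={"gene_id": str})
    ann_by_id = {
        row.cluster_id: ann_mod.FeatureAnnotation(
            cluster_id=row.cluster_id,
            gene_id=row.gene_id if isinstance(row.gene_id, str) and row.gene_id else None,
            category=row.category,
            signed_distance=None if pd.isna(row.signed_distance) else int(row.signed_distance),
            orientation=row.orientation if isinstance(row.orientation, str) else None,
        )
        for row in annotated.itertuples()
    }
    genes = {g.gene_id: g for g in read_gff3(config.gff3)}
    stages = config.stages
    all_calls = []
    for i in range(len(stages)):
        for j in range(i + 1, len(stages)):
            a, b = stages[i], stages[j]
            calls = shf.detect_promoter_shifts(
                clusters, ann_by_id, a, b,
                min_tpm=config.shift_min_tpm, min_fold=config.shift_min_fold,
            )
            for call in calls:
                call.consequence = shf.classify_shift_consequence(
                    call, genes.get(call.gene_id)
                )
                all_calls.append(call)
    df = pd.DataFrame([dataclasses.asdict(c) for c in all_calls])
    if not len(df):
        df = pd.DataFrame(
            columns=[f.name for f in dataclasses.fields(shf.ShiftCall)]
        )
    df.to_csv(wd / "shifts.tsv", sep="\t", index=False)
    logger.info("%d shift calls across stage pairs", len(df))


def stage_report(config: PipelineConfig) -> dict:
    """Assemble the catalog TSV, the machine-readable summary and the
    human-readable report; cross-checks counts against the catalog."""
    wd = _wd(config)
    consensus = pd.read_csv(wd / "consensus.tsv", sep="\t", dtype={"chrom": str})
    annotated = pd.read_csv(wd / "annotated.tsv", sep="\t", dtype={"gene_id": str})
    features = pd.read_csv(wd / "features.tsv", sep="\t")
    topscore = pd.read_csv(wd / "topscore.tsv", sep="\t", dtype={"gene_id": str})
    tau = pd.read_csv(wd / "tau.tsv", sep="\t", dtype={"gene_id": str})
    shifts_df = pd.read_csv(wd / "shifts.tsv", sep="\t", dtype={"gene_id": str})
    cluster_counts = json.loads((wd / "cluster_counts.json").read_text())
    features_meta = json.loads((wd / "features_meta.json").read_text())

    catalog = consensus.merge(annotated, on="cluster_id")
    catalog = catalog.merge(features, on="cluster_id", how="left")
    catalog = catalog.merge(
        topscore[["gene_id", "topscore"]], on="gene_id", how="left"
    )
    catalog = catalog.merge(tau[["gene_id", "tau"]], on="gene_id", how="left")
    # secondary clusters inherit no gene-level scores
    catalog.loc[~catalog["is_primary"].astype(bool), ["topscore", "tau"]] = np.nan
    write_catalog(catalog, wd / "catalog.tsv")

    primary = catalog[catalog["is_primary"].astype(bool)].copy()
    secondary = catalog[~catalog["is_primary"].astype(bool)]
    n_genes_assoc = annotated[
        (annotated["category"] != "unassociated") & (annotated["gene_id"] != "")
    ]["gene_id"].nunique()
    if len(primary) != n_genes_assoc:
        raise AssertionError(
            "catalog inconsistency: primary count != genes with associated clusters"
        )

    conc_dists = primary["signed_distance"].dropna().astype(int)
    try:
        concordance = ann_mod.tss_concordance(
            conc_dists, thresholds=config.concordance_thresholds
        )
    except ValueError:
        concordance = {t: float("nan") for t in config.concordance_thresholds}

    arch_counts = (
        primary["architecture"].value_counts().sort_index().to_dict()
        if "architecture" in primary
        else {}
    )
    summary = {
        "config": config.to_dict(),
        "per_stage": cluster_counts,
        "n_consensus_clusters": int(len(consensus)),
        "n_primary": int(len(primary)),
        "n_secondary": int(len(secondary)),
        "category_counts": {
            str(k): int(v)
            for k, v in annotated["category"].value_counts().sort_index().items()
        },
        "architecture_composition_primary": {str(k): int(v) for k, v in arch_counts.items()},
        "tata_fraction_primary": float(primary["tata"].mean()) if len(primary) else float("nan"),
        "tata_fraction_primary_lenient": (
            float(primary["tata_lenient"].mean()) if len(primary) else float("nan")
        ),
        "tata_positional_mode": features_meta.get("tata_positional_mode"),
        "concordance": {str(k): v for k, v in concordance.items()},
        "n_top_candidates": int(topscore["is_top_candidate"].sum()) if len(topscore) else 0,
        "shift_counts": (
            shifts_df.groupby(["stage_a", "stage_b"]).size().to_dict()
            if len(shifts_df)
            else {}
        ),
        "shift_consequences": (
            {
                str(k): int(v)
                for k, v in shifts_df["consequence"].value_counts().sort_index().items()
            }
            if len(shifts_df)
            else {}
        ),
        "mean_shift_distance": (
            float(shifts_df["shift_distance"].mean()) if len(shifts_df) else float("nan")
        ),
    }
    if config.te_bed:
        te = read_bed6(config.te_bed)
        pos = list(zip(primary["chrom"], primary["dominant_pos"].astype(int)))
        groups = ["TATA+" if t else "TATA-" for t in primary["tata"]]
        summary["te_overlap_fraction"] = mot.te_overlap_fraction(
            pos, te, flank=config.flank, groups=groups
        )
    summary["shift_counts"] = {
        f"{a}x{b}": int(v) for (a, b), v in summary["shift_counts"].items()
    }
    (wd / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True, default=str))
    _write_report(wd, summary)
    return summary


def _write_report(wd: Path, summary: dict) -> None:
    lines = ["promkit pipeline report", "=" * 24, ""]
    lines.append(f"consensus clusters: {summary['n_consensus_clusters']}")
    lines.append(f"primary promoters:  {summary['n_primary']}")
    lines.append(f"secondary clusters: {summary['n_secondary']}")
    lines.append("")
    lines.append("per-stage tag clusters:")
    for stage, c in sorted(summary["per_stage"].items()):
        lines.append(
            f"  {stage}: {c['tag_clusters_raw']} raw -> "
            f"{c['tag_clusters_filtered']} after TPM filters"
        )
    lines.append("")
    lines.append("feature categories:")
    for cat, n in sorted(summary["category_counts"].items()):
        lines.append(f"  {cat}: {n}")
    lines.append("")
    lines.append(
        "TATA fraction (primary, strict p): "
        f"{summary['tata_fraction_primary']:.3f} "
        f"(lenient: {summary['tata_fraction_primary_lenient']:.3f})"
    )
    lines.append(f"TATA positional mode: {summary['tata_positional_mode']}")
    lines.append("architecture composition (primary):")
    for label, n in sorted(summary["architecture_composition_primary"].items()):
        lines.append(f"  {label}: {n}")
    lines.append("")
    lines.append("dominant-CTSS / aTSS concordance (cumulative fractions):")
    for t, f in sorted(summary["concordance"].items(), key=lambda kv: int(kv[0])):
        lines.append(f"  within {t} bp: {f:.3f}")
    lines.append("")
    lines.append(f"TOP candidates (TOPscore > 3): {summary['n_top_candidates']}")
    lines.append("promoter shifts per stage pair:")
    for pair, n in sorted(summary["shift_counts"].items()):
        lines.append(f"  {pair}: {n}")
    for cons, n in sorted(summary["shift_consequences"].items()):
        lines.append(f"  consequence {cons}: {n}")
    if "te_overlap_fraction" in summary:
        lines.append("")
        lines.append("TE overlap within +/-50 bp of TSS:")
        for grp, f in sorted(summary["te_overlap_fraction"].items()):
            lines.append(f"  {grp}: {f:.3f}")
    (wd / "report.txt").write_text("\n".join(lines) + "\n")


STAGE_ORDER = [
    ("cluster", stage_cluster),
    ("consensus", stage_consensus),
    ("annotate", stage_annotate),
    ("features", stage_features),
    ("topscore", stage_topscore),
    ("tau", stage_tau),
    ("shifts", stage_shifts),
    ("report", stage_report),
]


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage in order; returns the summary dict."""
    summary: dict = {}
    for name, fn in STAGE_ORDER:
        logger.info("running stage: %s", name)
        result = fn(config)
        if name == "report":
            summary = result
    return summary
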