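"""Synthetic-data generator: determinism, planted-sequence consistency,
library-size calibration and filterable noise."""

import numpy as np
import pandas as pd
import pytest

from promkit.clustering import cluster_and_quantify, filter_clusters
from promkit.io_formats import revcomp
from promkit.motifs import TATA_FAMILY, YPATCH_CONSENSUS
from promkit.simulate import (
    ClassMixture,
    SimulationConfig,
    simulate_ctss_counts,
    simulate_dataset,
    simulate_genome_and_genes,
    write_dataset,
)


def _fetch_local(genome, row, t_start, length):
    """Transcribed-strand sequence at TSS-local offsets [t_start, ...)."""
    tss = int(row["aTSS"])
    if row["strand"] == "+":
        return genome.fetch(row["chrom"], tss + t_start, tss + t_start + length - 1, "+")
    return genome.fetch(row["chrom"], tss - t_start - length + 1, tss - t_start, "-")


class TestDeterminism:
    def test_outputs_byte_identical_for_fixed_seed(self, tmp_path):
        cfg = SimulationConfig(seed=5, n_genes=20)
        for d in ("a", "b"):
            write_dataset(simulate_dataset(SimulationConfig(seed=5, n_genes=20)), tmp_path / d)
        for f in sorted((tmp_path / "a").iterdir()):
            assert f.read_bytes() == (tmp_path / "b" / f.name).read_bytes(), f.name

    def test_different_seeds_differ(self, tmp_path):
        g1, _, _, _ = simulate_genome_and_genes(SimulationConfig(seed=1, n_genes=5))
        g2, _, _, _ = simulate_genome_and_genes(SimulationConfig(seed=2, n_genes=5))
        assert g1.sequence("chr1") != g2.sequence("chr1")


@pytest.fixture(scope="module")
def sim():
    cfg = SimulationConfig(seed=11, n_genes=120)
    genome, genes, truth, te = simulate_genome_and_genes(cfg)
    return cfg, genome, genes, truth


class TestPlantedSequences:
    def test_truth_joins_gene_models(self, sim):
        _, _, genes, truth = sim
        assert len(truth) == len(genes)
        by_id = {g.gene_id: g for g in genes}
        for _, row in truth.iterrows():
            assert by_id[row["gene_id"]].aTSS == row["aTSS"]
            assert by_id[row["gene_id"]].strand == row["strand"]

    def test_tata_genes_carry_family_member_at_minus32(self, sim):
        _, genome, _, truth = sim
        tata = truth[truth["class"] == "tata_sharp"]
        assert len(tata) > 0
        for _, row in tata.iterrows():
            assert _fetch_local(genome, row, -32, 8) in TATA_FAMILY
            assert _fetch_local(genome, row, -1, 2) == "CA"

    def test_non_tata_genes_have_no_family_match_in_band(self, sim):
        _, genome, _, truth = sim
        for _, row in truth[truth["class"] != "tata_sharp"].iterrows():
            window = _fetch_local(genome, row, -40, 29)
            assert not any(
                window[i : i + 8] in TATA_FAMILY for i in range(len(window) - 7)
            )

    def test_ypatch_genes_carry_consensus(self, sim):
        _, genome, _, truth = sim
        yp = truth[truth["class"] == "ypatch"]
        assert len(yp) > 0
        for _, row in yp.iterrows():
            off = int(row["ypatch_offset"])
            planted = _fetch_local(genome, row, off, 10)
            # the -1 initiator base may overwrite the final consensus base
            mismatches = sum(a != b for a, b in zip(planted, YPATCH_CONSENSUS))
            assert mismatches <= 1

    def test_top_genes_carry_tract(self, sim):
        _, genome, _, truth = sim
        top = truth[truth["class"] == "top"]
        assert len(top) > 0
        for _, row in top.iterrows():
            L = int(row["top_tract_len"])
            assert 5 <= L <= 13
            tract = _fetch_local(genome, row, 0, L + 1)
            assert tract[0] == "C"
            assert all(b in "CT" for b in tract[:L])
            assert tract[L] not in "CT"

    def test_singleton_genes_have_splice_acceptor(self, sim):
        _, genome, _, truth = sim
        sub = truth[truth["class"] == "intron_singleton"]
        assert len(sub) > 0
        for _, row in sub.iterrows():
            assert _fetch_local(genome, row, 797, 3) == "CAG"

    def test_shifted_genes_record_distance_near_500(self, sim):
        cfg, _, _, truth = sim
        sub = truth[truth["class"] == "shifted"]
        assert len(sub) > 0
        assert (abs(sub["shift_distance"] - 500) <= cfg.shift_jitter).all()
        for s in cfg.stages[1:]:
            assert (sub[f"dom_{s}"] == sub["shift_pos_b"]).all()

    def test_pure_tata_mixture(self):
        cfg = SimulationConfig(
            seed=2, n_genes=15,
            mixture=ClassMixture(tata_sharp=1.0, broad=0, ypatch=0, top=0,
                                 intron_singleton=0, shifted=0),
        )
        _, _, truth, _ = simulate_genome_and_genes(cfg)
        assert (truth["class"] == "tata_sharp").all()
        assert (truth["tata_offset"] == -32).all()

    def test_class_counts_near_binomial_expectation(self):
        cfg = SimulationConfig(seed=13, n_genes=500)
        _, _, truth, _ = simulate_genome_and_genes(cfg)
        n_tata = int((truth["class"] == "tata_sharp").sum())
        # binomial(500, 0.2): 3 sigma is ~27
        assert abs(n_tata - 100) < 30

    def test_genome_too_short_is_error(self):
        with pytest.raises(ValueError, match="too short"):
            SimulationConfig(seed=0, n_genes=100, chrom_length=1000)


class TestCounts:
    def test_library_size_calibrated(self):
        cfg = SimulationConfig(seed=4, n_genes=80)
        genome, genes, truth, _ = simulate_genome_and_genes(cfg)
        tables = simulate_ctss_counts(cfg, truth, genes)
        for table in tables.values():
            assert table.total_count == pytest.approx(cfg.library_size, rel=0.05)

    def test_noise_only_config_removed_by_filters(self):
        cfg = SimulationConfig(seed=6, n_genes=0, n_noise_positions=150)
        genome, genes, truth, _ = simulate_genome_and_genes(cfg)
        tables = simulate_ctss_counts(cfg, truth, genes)
        for table in tables.values():
            # noise positions are sparse singletons; every resulting cluster
            # is a singleton far below the TPM-5 floor at this library size
            table.library_size = cfg.library_size
            tcs = cluster_and_quantify(table)
            assert tcs  # noise did produce raw clusters
            assert filter_clusters(tcs) == []

    def test_sharp_promoters_have_small_iqw(self):
        cfg = SimulationConfig(
            seed=8, n_genes=30, sharp_sigma=1.0,
            mixture=ClassMixture(tata_sharp=1.0, broad=0, ypatch=0, top=0,
                                 intron_singleton=0, shifted=0),
        )
        genome, genes, truth, _ = simulate_genome_and_genes(cfg)
        tables = simulate_ctss_counts(cfg, truth, genes)
        tcs = cluster_and_quantify(tables[("stage1", 1)])
        big = [tc for tc in tcs if tc.tag_count > 1000]
        assert len(big) == 30
        assert np.mean([tc.iqw <= 5 for tc in big]) >= 0.95

    def test_replicates_share_expected_profile(self):
        cfg = SimulationConfig(seed=9, n_genes=150)
        genome, genes, truth, _ = simulate_genome_and_genes(cfg)
        tables = simulate_ctss_counts(cfg, truth, genes)
        from promkit.clustering import replicate_consistency_filter

        r1 = cluster_and_quantify(tables[("stage1", 1)])
        r2 = cluster_and_quantify(tables[("stage1", 2)])
        strong1 = [(tc.start, tc.end) for tc in r1 if tc.tag_count > 500 and tc.strand == "+"]
        strong2 = [(tc.start, tc.end) for tc in r2 if tc.tag_count > 500 and tc.strand == "+"]
        kept = replicate_consistency_filter(strong1, strong2)
        # nearly all strong true-promoter regions are replicate-consistent
        covered = sum(
            any(ks <= s and e <= ke for ks, ke in kept) for s, e in strong1
        )
        assert covered / len(strong1) >= 0.95
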