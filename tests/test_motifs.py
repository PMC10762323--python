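"""Promoter windows, PWM scans with exact p-values, architecture calls."""

import itertools

import numpy as np
import pytest

from promkit.io_formats import GenomeSequence, IntervalRecord, revcomp
from promkit.motifs import (
    TATA_FAMILY,
    YPATCH_CONSENSUS,
    PromoterWindow,
    build_pwm,
    classify_architecture,
    default_tata_pwm,
    dinucleotide_matrix,
    extract_window,
    index_to_offset,
    initiator_class,
    load_pwm,
    motif_position_profile,
    offset_to_index,
    pwm_scan,
    te_overlap_fraction,
    ypatch_scan,
)


class TestWindow:
    def test_extraction_plus(self):
        g = GenomeSequence({"c1": "AAACGTTT"})
        w = extract_window(g, "c1", 5, "+", flank=2)
        assert w.seq == "ACGTT"
        assert w.base(+1) == "G"
        assert w.base(-1) == "C"

    def test_extraction_minus_reverse_complements(self):
        g = GenomeSequence({"c1": "AAACGTTT"})
        w = extract_window(g, "c1", 5, "-", flank=2)
        assert w.seq == revcomp("ACGTT") == "AACGT"
        assert w.base(+1) == "C"

    def test_flank_zero_is_single_tss_base(self):
        g = GenomeSequence({"c1": "AAACGTTT"})
        w = extract_window(g, "c1", 5, "+", flank=0)
        assert w.seq == "G" and w.base(+1) == "G"

    def test_contig_edge_returns_none(self):
        g = GenomeSequence({"c1": "AAACGTTT"})
        assert extract_window(g, "c1", 2, "+", flank=3) is None
        assert extract_window(g, "c1", 7, "+", flank=3) is None

    def test_offset_index_mapping_skips_zero(self):
        assert offset_to_index(-1, 50) == 49
        assert offset_to_index(+1, 50) == 50
        assert index_to_offset(49, 50) == -1
        assert index_to_offset(50, 50) == +1
        with pytest.raises(ValueError):
            offset_to_index(0, 50)

    def test_minus_strand_scan_equals_plus_of_revcomp_genome(self):
        rng = np.random.default_rng(2)
        seq = "".join(rng.choice(list("ACGT"), size=201))
        g = GenomeSequence({"c": seq})
        g_rc = GenomeSequence({"c": revcomp(seq)})
        pos = 101
        w_minus = extract_window(g, "c", pos, "-", flank=50)
        w_plus = extract_window(g_rc, "c", len(seq) - pos + 1, "+", flank=50)
        assert w_minus.seq == w_plus.seq
        pwm = default_tata_pwm()
        hits_minus = pwm_scan(w_minus, pwm, p_threshold=1e-2)
        hits_plus = pwm_scan(w_plus, pwm, p_threshold=1e-2)
        assert [(h.start_offset, h.score) for h in hits_minus] == [
            (h.start_offset, h.score) for h in hits_plus
        ]


class TestInitiator:
    def _window(self, m1, p1):
        return PromoterWindow(seq="A" * 49 + m1 + p1 + "A" * 50, flank=50)

    @pytest.mark.parametrize(
        "m1,p1,expected",
        [
            ("C", "A", "CA"),
            ("C", "G", "CG"),
            ("T", "G", "TG"),
            ("T", "A", "other-PyPu"),
            ("C", "C", "non-PyPu"),
            ("G", "G", "non-PyPu"),
        ],
    )
    def test_classes(self, m1, p1, expected):
        cls, ambiguous = initiator_class(self._window(m1, p1))
        assert cls == expected and not ambiguous

    def test_n_flags_ambiguous(self):
        cls, ambiguous = initiator_class(self._window("N", "A"))
        assert cls == "non-PyPu" and ambiguous


class TestBuildPwm:
    def test_pseudocount_formula(self):
        pwm = build_pwm(["TATAAAT"] * 4)
        # matched base: (4 + 0.25) / (4 + 1) = 0.85
        consensus_probs = pwm.probs.max(axis=1)
        assert np.allclose(consensus_probs, 0.85)
        assert np.allclose(pwm.probs.sum(axis=1), 1.0)

    def test_uniform_background_log_odds(self):
        pwm = build_pwm(["TATAAAT"] * 4)
        assert np.allclose(pwm.log_odds.max(axis=1), np.log2(0.85 / 0.25))

    def test_too_few_sequences_is_error(self):
        with pytest.raises(ValueError):
            build_pwm([])
        with pytest.raises(ValueError):
            build_pwm(["ACGT"])

    def test_length_mismatch_is_error(self):
        with pytest.raises(ValueError):
            build_pwm(["ACGT", "ACG"])


def enumerate_pvalues(pwm):
    """Exhaustive oracle: p(s) over every possible motif-length sequence,
    weighting sequences by the background distribution."""
    L = pwm.length
    scores = pwm.int_scores
    bg = pwm.background
    all_scores = []
    weights = []
    for bases in itertools.product(range(4), repeat=L):
        all_scores.append(sum(int(scores[i, b]) for i, b in enumerate(bases)))
        w = 1.0
        for b in bases:
            w *= bg[b]
        weights.append(w)
    all_scores = np.array(all_scores)
    weights = np.array(weights)
    return all_scores, weights


class TestExactPvalues:
    @pytest.mark.parametrize("pwm_name", ["tata", "random5"])
    def test_dp_matches_exhaustive_enumeration(self, pwm_name):
        if pwm_name == "tata":
            pwm = default_tata_pwm()
        else:
            rng = np.random.default_rng(4)
            seqs = ["".join(rng.choice(list("ACGT"), size=5)) for _ in range(6)]
            pwm = build_pwm(seqs)
        all_scores, weights = enumerate_pvalues(pwm)
        for s in np.unique(all_scores):
            expected = weights[all_scores >= s].sum()
            assert pwm.pvalue(int(s)) == pytest.approx(expected, rel=1e-12)

    def test_minimum_score_has_pvalue_one(self):
        pwm = default_tata_pwm()
        smin = int(pwm.int_scores.min(axis=1).sum())
        assert pwm.pvalue(smin) == 1.0
        assert pwm.pvalue(smin - 1000) == 1.0

    def test_family_members_pass_1e4_and_one_substitution_fails(self):
        pwm = default_tata_pwm()
        for member in TATA_FAMILY:
            assert pwm.pvalue(pwm.int_score(member)) <= 1e-4
        mutated = "TGTAAATA"
        assert pwm.pvalue(pwm.int_score(mutated)) > 1e-4


class TestScans:
    def _window_with(self, insert, at_offset, flank=50, fill="C"):
        seq = list(fill * (2 * flank + 1))
        i = offset_to_index(at_offset, flank)
        seq[i : i + len(insert)] = list(insert)
        return PromoterWindow(seq="".join(seq), flank=flank)

    def test_planted_tata_found_at_minus32(self):
        w = self._window_with("TATAAATA", -32)
        hits = pwm_scan(w, default_tata_pwm(), p_threshold=1e-4)
        assert [h.start_offset for h in hits] == [-32]

    def test_threshold_one_reports_every_position(self):
        w = self._window_with("TATAAATA", -32)
        hits = pwm_scan(w, default_tata_pwm(), p_threshold=1.0)
        assert len(hits) == len(w.seq) - default_tata_pwm().length + 1

    def test_ypatch_consensus_and_reverse_complement_hit(self):
        w_fwd = self._window_with(YPATCH_CONSENSUS, -20, fill="A")
        w_rc = self._window_with(revcomp(YPATCH_CONSENSUS), -20, fill="A")
        assert any(h.start_offset == -20 for h in ypatch_scan(w_fwd))
        assert any(h.start_offset == -20 for h in ypatch_scan(w_rc))

    def test_all_a_window_has_no_ypatch(self):
        w = PromoterWindow(seq="A" * 101, flank=50)
        assert ypatch_scan(w, p_threshold=1e-4) == []

    def test_position_profile_mode(self):
        w = self._window_with("TATAAATA", -32)
        hits = pwm_scan(w, default_tata_pwm(), 1e-4)
        hist, mode = motif_position_profile(hits * 5)
        assert mode == -32 and hist[-32] == 5

    def test_empty_profile_mode_flagged(self):
        hist, mode = motif_position_profile([])
        assert mode is None and all(v == 0 for v in hist.values())


class TestDinucleotideMatrix:
    def test_planted_dinucleotide_frequency(self):
        w1 = PromoterWindow(seq="A" * 49 + "CA" + "A" * 50, flank=50)
        w2 = PromoterWindow(seq="A" * 49 + "CG" + "A" * 50, flank=50)
        m = dinucleotide_matrix([w1, w2])
        assert m.loc["CA", -1] == pytest.approx(0.5)
        assert m.loc["CG", -1] == pytest.approx(0.5)

    def test_columns_are_probability_distributions(self):
        rng = np.random.default_rng(9)
        windows = [
            PromoterWindow(seq="".join(rng.choice(list("ACGT"), size=101)), flank=50)
            for _ in range(20)
        ]
        m = dinucleotide_matrix(windows)
        assert np.allclose(m.sum(axis=0), 1.0)


class TestArchitecture:
    def _window(self, seq):
        return PromoterWindow(seq=seq, flank=50)

    def test_tata_with_ca_initiator(self):
        seq = list("C" * 101)
        i = offset_to_index(-32, 50)
        seq[i : i + 8] = list("TATAAATA")
        seq[offset_to_index(-1, 50)] = "C"
        seq[offset_to_index(+1, 50)] = "A"
        w = self._window("".join(seq))
        hits = pwm_scan(w, default_tata_pwm(), 1e-4)
        arch = classify_architecture(w, hits, [])
        assert arch.label == "TATA+/CA"

    def test_label_composition_with_ypatch(self):
        w = self._window("G" * 49 + "CG" + "G" * 50)
        arch = classify_architecture(w, [], [object()])
        assert arch.label == "TATA-/CG/Ypatch+"

    def test_tata_outside_positional_range_not_counted(self):
        seq = list("C" * 101)
        i = offset_to_index(-10, 50)
        seq[i : i + 8] = list("TATAAATA")
        w = self._window("".join(seq))
        hits = pwm_scan(w, default_tata_pwm(), 1e-4)
        assert any(h.start_offset == -10 for h in hits)
        arch = classify_architecture(w, hits, [])
        assert not arch.tata


class TestTeOverlap:
    def test_boundary_arithmetic(self):
        te = [IntervalRecord("c1", 960, 1100)]
        assert te_overlap_fraction([("c1", 1000)], te) == 1.0
        # window is [950, 1050]; TE starting at 1051 misses by one base
        te2 = [IntervalRecord("c1", 1051, 1100)]
        assert te_overlap_fraction([("c1", 1000)], te2) == 0.0
        te3 = [IntervalRecord("c1", 1050, 1100)]
        assert te_overlap_fraction([("c1", 1000)], te3) == 1.0

    def test_no_tes_gives_zero(self):
        assert te_overlap_fraction([("c1", 1000)], []) == 0.0

    def test_per_group_fractions(self):
        te = [IntervalRecord("c1", 960, 1100)]
        out = te_overlap_fraction(
            [("c1", 1000), ("c1", 5000)], te, groups=["TATA+", "TATA-"]
        )
        assert out == {"TATA+": 1.0, "TATA-": 0.0}


class TestPwmIO:
    def test_jaspar_roundtrip_matches_default(self, tmp_path):
        import importlib.resources as res

        shipped = res.files("promkit").joinpath("data/tata_tatawawa.jaspar")
        p = tmp_path / "tata.jaspar"
        p.write_text(shipped.read_text())
        pwm = load_pwm(p)
        assert np.allclose(pwm.probs, default_tata_pwm().probs)

    def test_meme_minimal_parsing(self, tmp_path):
        p = tmp_path / "m.meme"
        p.write_text(
            "MEME version 4\n\nALPHABET= ACGT\n\nMOTIF test\n"
            "letter-probability matrix: alength= 4 w= 4 nsites= 10\n"
            "0.97 0.01 0.01 0.01\n0.01 0.97 0.01 0.01\n"
            "0.01 0.01 0.97 0.01\n0.01 0.01 0.01 0.97\n"
        )
        pwm = load_pwm(p)
        assert pwm.length == 4
        best = "".join("ACGT"[i] for i in pwm.probs.argmax(axis=1))
        assert best == "ACGT"
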