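"""Aligner: local alignment vs an independent dynamic-programming oracle,
read scanning on both strands, co-linear merging, and MAF parsing."""
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import ampchimera as ac
from ampchimera._seq import random_dna, revcomp
from ampchimera.align import Match, filter_matches, read_maf
from ampchimera.synth import clean_spec, corrupt, expand_construct

from _oracles import gotoh_local_score


class TestLocalAlign:
    def test_perfect_self_match(self):
        score, qiv, tiv, ident = ac.local_align("ACGTACGT", "ACGTACGT")
        assert (score, qiv, tiv, ident) == (8, (0, 8), (0, 8), 1.0)

    def test_all_mismatch_scores_at_most_one(self):
        score, *_ = ac.local_align("AAAA", "TTTT")
        assert score <= 1

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            ac.local_align("", "ACGT")

    def test_gapped_alignment_scores_match_oracle_on_random_pairs(self):
        rng = np.random.default_rng(2024)
        for _ in range(100):
            q = random_dna(rng, int(rng.integers(1, 31)))
            t = random_dna(rng, int(rng.integers(1, 31)))
            score, *_ = ac.local_align(q, t)
            assert score == gotoh_local_score(q, t)

    def test_identity_counts_gap_columns(self):
        # target carries a 3-base insertion: a gap (cost 2 + 3*1 = 5) beats
        # the ungapped alternative (3 mismatches + 3 lost matches = 6)
        q = "AAAAAACC" + "T" * 8
        t = "AAAAAACC" + "GGG" + "T" * 8
        score, _, _, ident = ac.local_align(q, t)
        assert score == 16 - 5
        assert ident == pytest.approx(16 / 19)


class TestScanRead:
    def test_exact_clean_construct(self, panel, bcmap, scheme):
        seq = ac.build_construct(clean_spec("Ifnb1", "overnight", bcmap), panel)
        ms = ac.scan_read(("r1", seq), panel, scheme)
        key = [(m.target, m.read_start, m.read_end, m.orientation) for m in ms]
        assert key == [("NB05", 0, 24, "fwd"), ("Ifnb1", 24, 624, "fwd"),
                       ("NB05", 624, 648, "fwd")]
        assert all(m.identity == 1.0 for m in ms)

    def test_reverse_complement_mirrors_coordinates(self, panel, bcmap, scheme):
        seq = ac.build_construct(clean_spec("Ifnb1", "overnight", bcmap), panel)
        ms = ac.scan_read(("r1", revcomp(seq)), panel, scheme)
        key = [(m.target, m.read_start, m.read_end, m.orientation) for m in ms]
        assert key == [("NB05", 0, 24, "rev"), ("Ifnb1", 24, 624, "rev"),
                       ("NB05", 624, 648, "rev")]

    def test_corrupted_amplicon_recovered(self, panel, bcmap, scheme):
        rng = np.random.default_rng(77)
        seq = ac.build_construct(clean_spec("Actb", "quick", bcmap), panel)
        noisy = corrupt(seq, (0.05, 0.0, 0.0), rng)
        ms = ac.scan_read(("r1", noisy), panel, scheme)
        actb = [m for m in ms if m.target == "Actb"]
        assert len(actb) == 1 and actb[0].identity >= 0.9

    def test_strand_symmetry_on_error_free_construct(self, panel, bcmap, scheme):
        seq = ac.build_construct(clean_spec("Ifna", "overnight", bcmap, is_2d=True), panel)
        fwd = ac.scan_read(("r", seq), panel, scheme)
        rev = ac.scan_read(("r", revcomp(seq)), panel, scheme)
        flip = {"fwd": "rev", "rev": "fwd"}
        n = len(seq)
        mirrored = sorted((m.target, flip[m.orientation], n - m.read_end, n - m.read_start)
                          for m in fwd)
        assert mirrored == sorted((m.target, m.orientation, m.read_start, m.read_end)
                                  for m in rev)

    def test_corruption_never_increases_best_score(self, panel, bcmap, scheme):
        seq = ac.build_construct(clean_spec("Ifna", "overnight", bcmap), panel)
        clean_best = max(m.score for m in ac.scan_read(("r", seq), panel, scheme)
                         if m.target == "Ifna")
        for seed in range(8):
            rng = np.random.default_rng(seed)
            noisy = corrupt(seq, (0.05, 0.03, 0.03), rng)
            hits = [m.score for m in ac.scan_read(("r", noisy), panel, scheme)
                    if m.target == "Ifna"]
            assert max(hits, default=0) <= clean_best


def _m(target, start, end, orientation="fwd", kind="amplicon", score=100,
       identity=0.95, ts=0, te=None):
    if te is None:
        te = ts + (end - start)
    return Match("r", target, kind, start, end, orientation, score, identity, ts, te)


class TestMergeColinear:
    def test_single_match_unchanged(self):
        ms = [_m("Ifna", 10, 200)]
        assert ac.merge_colinear(ms) == ms

    def test_fragments_of_one_alignment_merge(self):
        ms = [_m("Ifna", 10, 200, ts=0, te=190),
              _m("Ifna", 205, 530, ts=195, te=520)]
        out = ac.merge_colinear(ms, max_gap=50)
        assert len(out) == 1
        m = out[0]
        assert (m.read_start, m.read_end) == (10, 530)
        assert (m.target_start, m.target_end) == (0, 520)
        assert m.score == 200

    def test_distant_fragments_not_merged(self):
        ms = [_m("Ifna", 10, 200, ts=0, te=190),
              _m("Ifna", 600, 900, ts=195, te=495)]
        assert len(ac.merge_colinear(ms, max_gap=50)) == 2

    def test_repeated_target_not_merged(self):
        # second copy restarts the target: a repeated-amplicon chimera
        ms = [_m("Actb", 24, 548, ts=0, te=524),
              _m("Actb", 572, 1096, ts=0, te=524)]
        assert len(ac.merge_colinear(ms, max_gap=50)) == 2

    def test_reverse_orientation_merges_descending_target(self):
        ms = [_m("Ifna", 10, 200, orientation="rev", ts=330, te=520),
              _m("Ifna", 205, 530, orientation="rev", ts=0, te=325)]
        out = ac.merge_colinear(ms, max_gap=50)
        assert len(out) == 1
        assert (out[0].target_start, out[0].target_end) == (0, 520)

    def test_unsorted_input_rejected(self):
        ms = [_m("Ifna", 205, 530), _m("Ifna", 10, 200)]
        with pytest.raises(ValueError):
            ac.merge_colinear(ms)

    @given(st.lists(
        st.tuples(st.integers(0, 900), st.integers(1, 120), st.integers(0, 900)),
        min_size=0, max_size=6))
    @settings(deadline=None, derandomize=True)
    def test_idempotent(self, raw):
        ms = sorted(
            (_m("Ifna", s, s + ln, ts=t, te=t + ln) for s, ln, t in raw),
            key=lambda m: m.read_start)
        once = ac.merge_colinear(ms)
        assert ac.merge_colinear(once) == once


class TestFilterMatches:
    def test_contained_barcode_dropped_flanking_kept(self):
        ms = [_m("NB04", 0, 24, kind="barcode", score=20),
              _m("Actb", 24, 548, ts=0, te=524),
              _m("NB05", 200, 220, kind="barcode", score=12),
              _m("NB04", 548, 572, kind="barcode", score=20)]
        ms.sort(key=lambda m: m.read_start)
        out = filter_matches(ms)
        assert [m.target for m in out] == ["NB04", "Actb", "NB04"]

    def test_same_locus_competition_keeps_best(self):
        ms = [_m("NB04", 0, 24, kind="barcode", score=20),
              _m("NB05", 2, 20, kind="barcode", score=12)]
        out = filter_matches(ms)
        assert [m.target for m in out] == ["NB04"]

    def test_distinct_loci_barcodes_both_kept(self):
        ms = [_m("NB04", 0, 24, kind="barcode", score=20),
              _m("NB05", 100, 124, kind="barcode", score=20)]
        assert len(filter_matches(ms)) == 2


class TestReadMaf:
    def _write(self, tmp_path, text):
        p = tmp_path / "aln.maf"
        p.write_text(text)
        return p

    def test_plus_strand_passthrough(self, tmp_path):
        p = self._write(tmp_path, (
            "a score=95\n"
            "s Actb 0 100 + 524 " + "A" * 100 + "\n"
            "s read1 10 100 + 500 " + "A" * 100 + "\n"
        ))
        (m,) = read_maf(p)
        assert (m.read_start, m.read_end, m.orientation) == (10, 110, "fwd")
        assert (m.target_start, m.target_end) == (0, 100)
        assert m.score == 95 and m.identity == 1.0

    def test_minus_strand_forward_projection(self, tmp_path):
        p = self._write(tmp_path, (
            "a score=80\n"
            "s Actb 5 100 + 524 " + "C" * 100 + "\n"
            "s read1 10 100 - 500 " + "C" * 100 + "\n"
        ))
        (m,) = read_maf(p)
        # srcSize - start - size = 500 - 10 - 100 = 390
        assert (m.read_start, m.read_end, m.orientation) == (390, 490, "rev")

    def test_empty_file(self, tmp_path):
        assert read_maf(self._write(tmp_path, "")) == []

    def test_malformed_block_names_index(self, tmp_path):
        p = self._write(tmp_path, (
            "a score=10\n"
            "s Actb 0 4 + 524 ACGT\n"
            "s read1 0 4 + 50 ACGT\n"
            "a score=11\n"
            "s Actb 0 4 + 524 ACGT\n"
        ))
        with pytest.raises(ValueError, match="block 1"):
            read_maf(p)

    def test_kind_resolved_from_panel(self, tmp_path, panel):
        p = self._write(tmp_path, (
            "a score=24\n"
            "s NB04 0 24 + 24 " + "G" * 24 + "\n"
            "s read9 0 24 + 600 " + "G" * 24 + "\n"
        ))
        (m,) = read_maf(p, panel)
        assert m.kind == "barcode"
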