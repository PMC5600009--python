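"""Classification: the four chimera rules, the 2D-ambiguity exclusion,
batch attribution, and agreement with a literal rule enumerator."""
import numpy as np
import pytest

import ampchimera as ac
from ampchimera.align import Match
from ampchimera.classify import ReadAnnotation, categorize, mixed_batch_reads
from ampchimera.panel import BarcodeMap, PanelEntry, ReferencePanel

from _oracles import literal_chimera_rules


def _m(target, kind, start, end, orientation="fwd"):
    return Match("r", target, kind, start, end, orientation, 50, 0.9, 0, end - start)


def _ann(*matches):
    ms = sorted(matches, key=lambda m: m.read_start)
    return ReadAnnotation("r", ms, ms[-1].read_end if ms else 0)


class TestGeneIdentity:
    def test_family_member_collapses_to_gene(self):
        panel = ReferencePanel([
            PanelEntry("Ifna2", "amplicon", "Ifna", "ACGT" * 10),
            PanelEntry("Actb", "amplicon", "Actb", "ACGT" * 10),
        ])
        m = _m("Ifna2", "amplicon", 0, 40)
        assert ac.gene_identity(m, panel) == "Ifna"
        assert ac.gene_identity(_m("Actb", "amplicon", 0, 40), panel) == "Actb"

    def test_non_amplicon_match_rejected(self, panel):
        with pytest.raises(ValueError):
            ac.gene_identity(_m("NB05", "barcode", 0, 24), panel)


class TestBatchOf:
    def test_default_map_assignments(self, bcmap):
        assert ac.batch_of("NB04", bcmap) == "overnight"
        assert ac.batch_of("NB05", bcmap) == "overnight"
        assert ac.batch_of("NB06", bcmap) == "quick"

    def test_unknown_barcode_errors(self, bcmap):
        with pytest.raises(KeyError, match="NB99"):
            ac.batch_of("NB99", bcmap)


class TestCategorize:
    def test_repeated_amplicon_most_frequent_category(self, panel, bcmap):
        call = categorize(_ann(
            _m("NB11", "barcode", 0, 24),
            _m("Actb", "amplicon", 24, 548),
            _m("Actb", "amplicon", 600, 1124),
        ), panel, bcmap)
        assert call.repeated_amplicon and call.definitive
        assert call.signature.counts_dict() == {"Ifna": 0, "Ifnb1": 0, "Actb": 2}
        assert call.signature.batches == frozenset({"overnight"})

    def test_two_opposite_orientations_excluded_as_2d(self, panel, bcmap):
        call = categorize(_ann(
            _m("Actb", "amplicon", 24, 548, "fwd"),
            _m("HP", "hairpin", 560, 620),
            _m("Actb", "amplicon", 640, 1164, "rev"),
        ), panel, bcmap)
        assert not call.definitive
        assert call.nonchimeric_class == "sequence_only"

    def test_multi_amplicon_and_multi_barcode_co_occur(self, panel, bcmap):
        call = categorize(_ann(
            _m("NB04", "barcode", 0, 24),
            _m("Ifna", "amplicon", 24, 559),
            _m("HP", "hairpin", 570, 630),
            _m("Ifnb1", "amplicon", 650, 1250),
            _m("NB05", "barcode", 1250, 1274),
        ), panel, bcmap)
        assert call.multi_amplicon and call.multi_barcode and call.definitive

    def test_clean_construct_nonchimeric(self, panel, bcmap):
        call = categorize(_ann(
            _m("NB05", "barcode", 0, 24),
            _m("Ifnb1", "amplicon", 24, 624),
            _m("NB05", "barcode", 624, 648),
        ), panel, bcmap)
        assert not call.definitive
        assert call.nonchimeric_class == "amplicon_and_barcode"

    def test_three_same_gene_matches_flag_when_two_share_direction(self, panel, bcmap):
        call = categorize(_ann(
            _m("Actb", "amplicon", 0, 500, "fwd"),
            _m("Actb", "amplicon", 520, 1020, "rev"),
            _m("Actb", "amplicon", 1040, 1540, "rev"),
        ), panel, bcmap)
        assert call.repeated_amplicon

    def test_barcode_amplicon_disagreement(self, panel, bcmap):
        call = categorize(_ann(
            _m("NB04", "barcode", 0, 24),       # assigned to Ifna
            _m("Actb", "amplicon", 24, 548),
            _m("NB04", "barcode", 548, 572),
        ), panel, bcmap)
        assert call.disagreement and not call.multi_barcode

    def test_unmapped_and_barcode_only_classes(self, panel, bcmap):
        assert categorize(_ann(), panel, bcmap).nonchimeric_class == "unmapped"
        call = categorize(_ann(_m("NB05", "barcode", 0, 24)), panel, bcmap)
        assert call.nonchimeric_class == "barcode_only"

    def test_unsorted_matches_rejected(self, panel, bcmap):
        ann = ReadAnnotation.__new__(ReadAnnotation)
        ann.read_id = "r"
        ann.matches = [_m("Actb", "amplicon", 100, 200), _m("NB05", "barcode", 0, 24)]
        ann.read_length = 200
        with pytest.raises(ValueError):
            categorize(ann, panel, bcmap)

    def test_agrees_with_literal_rule_enumerator(self, panel, bcmap):
        rng = np.random.default_rng(99)
        targets = [("Ifna", "amplicon"), ("Ifnb1", "amplicon"), ("Actb", "amplicon"),
                   ("NB04", "barcode"), ("NB05", "barcode"), ("NB11", "barcode"),
                   ("NB01", "barcode"), ("NB03", "barcode"), ("NB06", "barcode"),
                   ("HP", "hairpin"), ("LEADER", "leader")]
        for _ in range(1000):
            k = int(rng.integers(0, 6))
            ms = []
            pos = 0
            for _ in range(k):
                name, kind = targets[rng.integers(0, len(targets))]
                ln = int(rng.integers(20, 600))
                orient = "fwd" if rng.random() < 0.5 else "rev"
                ms.append(_m(name, kind, pos, pos + ln, orient))
                pos += ln + int(rng.integers(0, 30))
            call = categorize(_ann(*ms), panel, bcmap)
            expected = literal_chimera_rules(ms, panel, bcmap)
            assert call.flags == expected, (call.flags, expected, ms)
            assert call.definitive == any(expected.values())

    def test_partition_into_definitive_or_single_class(self, panel, bcmap):
        rng = np.random.default_rng(5)
        for _ in range(200):
            ms = []
            pos = 0
            for _ in range(int(rng.integers(0, 5))):
                name, kind = [("Ifna", "amplicon"), ("NB04", "barcode"),
                              ("NB06", "barcode"), ("HP", "hairpin")][rng.integers(0, 4)]
                ln = int(rng.integers(20, 500))
                ms.append(_m(name, kind, pos, pos + ln))
                pos += ln + 5
            call = categorize(_ann(*ms), panel, bcmap)
            assert call.definitive == (call.nonchimeric_class == "none")

    def test_orientation_invariance(self, panel, bcmap):
        ms = [
            _m("NB04", "barcode", 0, 24, "fwd"),
            _m("Ifna", "amplicon", 24, 559, "fwd"),
            _m("NB05", "barcode", 580, 604, "fwd"),
        ]
        n = 604
        flip = {"fwd": "rev", "rev": "fwd"}
        mirrored = sorted(
            (Match("r", m.target, m.kind, n - m.read_end, n - m.read_start,
                   flip[m.orientation], m.score, m.identity, m.target_start,
                   m.target_end) for m in ms),
            key=lambda m: m.read_start)
        a = categorize(_ann(*ms), panel, bcmap)
        b = categorize(ReadAnnotation("r", mirrored, n), panel, bcmap)
        assert a.flags == b.flags and a.signature == b.signature


class TestGeneratorCoverage:
    def test_each_mechanism_produces_its_hallmark_flag(self, panel, bcmap):
        """Every chimera mechanism the generator knows is reachable and
        carries its hallmark flag through scan -> merge -> classify on an
        error-free read."""
        import numpy as np

        from ampchimera.pipeline import annotate_reads
        from ampchimera.synth import FastqRead, SimParams, _chimera_spec, expand_construct

        hallmark = {
            "chimera_repeat": "repeated_amplicon",
            "chimera_multi_amplicon": "multi_amplicon",
            "chimera_multi_barcode": "multi_barcode",
            "chimera_disagreement": "disagreement",
        }
        rng = np.random.default_rng(1)
        params = SimParams()
        for mechanism, flag in hallmark.items():
            spec = _chimera_spec(mechanism, rng, params, bcmap)
            seq, _, _ = expand_construct(spec, panel)
            _, (ann,) = annotate_reads([FastqRead("r", seq)], panel,
                                       ac.ScoringScheme(), 50)
            call = categorize(ann, panel, bcmap)
            assert call.flags[flag], (mechanism, call.flags)
            assert call.definitive


class TestMixedBatch:
    def test_selection_by_batch_signature(self, panel, bcmap):
        both = categorize(_ann(
            _m("NB11", "barcode", 0, 24),
            _m("Actb", "amplicon", 24, 548),
            _m("NB06", "barcode", 548, 572),
        ), panel, bcmap)
        single = categorize(_ann(
            _m("NB11", "barcode", 0, 24),
            _m("Actb", "amplicon", 24, 548),
        ), panel, bcmap)
        assert mixed_batch_reads([both, single]) == [both.read_id]
        assert mixed_batch_reads([]) == []


class TestCallsRoundTrip:
    def test_csv_round_trip(self, panel, bcmap, tmp_path):
        calls = [
            categorize(_ann(
                _m("NB05", "barcode", 0, 24),
                _m("Ifnb1", "amplicon", 24, 624),
            ), panel, bcmap),
            categorize(_ann(
                _m("NB11", "barcode", 0, 24),
                _m("Actb", "amplicon", 24, 548),
                _m("Actb", "amplicon", 600, 1124),
            ), panel, bcmap),
        ]
        path = tmp_path / "calls.csv"
        ac.classify.write_calls(calls, path)
        back = ac.classify.read_calls(path)
        assert [c.flags for c in back] == [c.flags for c in calls]
        assert [c.signature for c in back] == [c.signature for c in calls]
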