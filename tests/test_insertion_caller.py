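"""Windowed calling, the two read thresholds, masking and validation."""

import warnings

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ripscan.discordant_scan import AnchorEvidence
from ripscan.insertion_caller import (
    InsertionCallSet,
    WindowKey,
    assign_window,
    call_insertions,
    copy_number,
    copy_number_by_family,
    mask_reference_windows,
    read_calls,
    validate_against_assembly,
    write_calls,
)
from ripscan.te_library import TEInterval


def ev(pos, family="ji", chrom="chr1", acc="a", te_seq="", anchor_seq=""):
    return AnchorEvidence(acc, family, chrom, pos, f"p{pos}", te_seq, anchor_seq)


class TestAssignWindow:
    @pytest.mark.parametrize(
        "pos,expected", [(0, 0), (9_999, 0), (10_000, 1), (123_456, 12)]
    )
    def test_examples(self, pos, expected):
        assert assign_window(pos) == expected

    def test_negative_position_rejected(self):
        with pytest.raises(ValueError):
            assign_window(-1)

    def test_zero_window_rejected(self):
        with pytest.raises(ValueError):
            assign_window(5, window_size=0)

    @given(st.integers(0, 10**9), st.integers(1, 10**6))
    @settings(max_examples=200, deadline=None)
    def test_window_covers_halfopen_range(self, pos, ws):
        w = assign_window(pos, ws)
        assert w * ws <= pos < (w + 1) * ws


class TestCallInsertions:
    def test_call_rule_is_strictly_more_than_three(self):
        four = [ev(100 + i) for i in range(4)]
        three = [ev(100 + i) for i in range(3)]
        assert len(call_insertions(four).calls) == 1
        assert len(call_insertions(three).calls) == 0

    def test_empty_evidence(self):
        cs = call_insertions([])
        assert cs.counts == {} and cs.calls == set()

    def test_mixed_accessions_rejected(self):
        with pytest.raises(ValueError, match="mixes accessions"):
            call_insertions([ev(1, acc="a"), ev(2, acc="b")])

    def test_insertion_point_is_lower_median(self):
        positions = [100, 200] + [300 + i for i in range(10)]
        cs = call_insertions([ev(p) for p in positions])
        key = WindowKey("ji", "chr1", 0)
        assert cs.calls == {key}
        assert cs.insertion_point[key] == sorted(positions)[(12 - 1) // 2]

    def test_families_are_distinct_loci(self):
        evidence = [ev(100 + i, family="ji") for i in range(4)] + [
            ev(200 + i, family="huck") for i in range(4)
        ]
        cs = call_insertions(evidence)
        assert {k.family for k in cs.calls} == {"ji", "huck"}

    def test_counts_match_bruteforce_oracle(self, rng):
        """Windowed counts equal a per-record brute-force loop exactly."""
        for _ in range(20):
            n = int(rng.integers(1, 300))
            evidence = [
                ev(int(rng.integers(0, 100_000)),
                   family=str(rng.choice(["a", "b"])),
                   chrom=str(rng.choice(["c1", "c2"])))
                for _ in range(n)
            ]
            # fix duplicate pair ids (irrelevant for counting)
            cs = call_insertions(evidence, window_size=7_000)
            brute: dict = {}
            for e in evidence:
                k = WindowKey(e.family, e.chrom, e.anchor_pos // 7_000)
                brute[k] = brute.get(k, 0) + 1
            assert cs.counts == brute

    def test_raising_min_reads_never_adds_calls(self, rng):
        evidence = [ev(int(rng.integers(0, 50_000))) for _ in range(200)]
        prev = None
        for mr in range(1, 10):
            calls = call_insertions(evidence, min_reads=mr).calls
            if prev is not None:
                assert calls <= prev
            prev = calls


class TestCopyNumber:
    def test_at_least_three_is_inclusive(self):
        cs = InsertionCallSet("a", counts={
            WindowKey("f", "c", 1): 3, WindowKey("f", "c", 2): 2, WindowKey("f", "c", 3): 5,
        })
        assert copy_number(cs) == 2

    def test_all_below_threshold(self):
        cs = InsertionCallSet("a", counts={WindowKey("f", "c", 1): 2})
        assert copy_number(cs) == 0

    def test_per_family_partition(self):
        cs = InsertionCallSet("a", counts={
            WindowKey("a", "c", 1): 4, WindowKey("b", "c", 1): 4,
        })
        assert copy_number_by_family(cs) == {"a": 1, "b": 1}

    def test_three_reads_counts_for_copy_number_but_not_called(self):
        """The two thresholds differ: >3 to call, >=3 for copy number."""
        cs = call_insertions([ev(100), ev(150), ev(200)])
        assert cs.calls == set()
        assert copy_number(cs) == 1


class TestMasking:
    def test_same_family_windows_dropped(self):
        cs = call_insertions([ev(100 + i) for i in range(4)] +
                             [ev(50_000 + i, family="huck") for i in range(4)])
        masked = mask_reference_windows(cs, [TEInterval("chr1", 0, 2_000, "ji", "Copia")])
        assert {k.family for k in masked.calls} == {"huck"}

    def test_other_family_untouched(self):
        cs = call_insertions([ev(100 + i) for i in range(4)])
        masked = mask_reference_windows(cs, [TEInterval("chr1", 0, 2_000, "huck", "Gypsy")])
        assert masked.calls == cs.calls

    def test_pad_extends_mask(self):
        cs = call_insertions([ev(10_100 + i) for i in range(4)])
        iv = TEInterval("chr1", 8_000, 9_000, "ji", "Copia")
        assert mask_reference_windows(cs, [iv], pad=0).calls != set()
        assert mask_reference_windows(cs, [iv], pad=1_500).calls == set()


class TestCallsIO:
    def test_round_trip(self, tmp_path):
        cs = call_insertions([ev(100 + i) for i in range(5)] + [ev(90_000)])
        p = tmp_path / "calls.tsv"
        write_calls(cs, p)
        back = read_calls(p)
        assert back.counts == cs.counts
        assert back.calls == cs.calls
        assert back.insertion_point == cs.insertion_point


@pytest.fixture(scope="module")
def two_insertion_toy():
    """Reference + a donor carrying two TE insertions, with evidence."""
    rng = np.random.default_rng(17)
    ref = "".join("ACGT"[i] for i in rng.integers(0, 4, 60_000))
    te = "".join("ACGT"[i] for i in rng.integers(0, 4, 1_200))
    p1, p2 = 15_000, 42_000
    donor = ref[:p1] + te + ref[p1:p2] + te + ref[p2:]
    evidence = []
    for p in (p1, p2):
        for j in range(5):
            anchor = ref[p - 220 + j * 10 : p - 120 + j * 10]
            te_mate = te[j * 20 : j * 20 + 100]
            evidence.append(
                AnchorEvidence("a", "ji", "chr1", p - 220 + j * 10, f"{p}:{j}",
                               te_mate, anchor)
            )
    cs = call_insertions(evidence)
    return dict(ref=ref, donor=donor, evidence=evidence, callset=cs)


class TestValidation:
    def test_donor_assembly_validates_fully(self, two_insertion_toy):
        t = two_insertion_toy
        frac = validate_against_assembly(t["callset"], t["evidence"], {"chr1": t["donor"]})
        assert frac == 1.0

    def test_insertion_free_reference_validates_nothing(self, two_insertion_toy):
        t = two_insertion_toy
        frac = validate_against_assembly(t["callset"], t["evidence"], {"chr1": t["ref"]})
        assert frac == 0.0

    def test_zero_flank_returns_none_with_warning(self, two_insertion_toy):
        t = two_insertion_toy
        with pytest.warns(UserWarning):
            assert validate_against_assembly(
                t["callset"], t["evidence"], {"chr1": t["donor"]}, flank=0
            ) is None

    def test_no_called_windows_returns_none(self, two_insertion_toy):
        t = two_insertion_toy
        empty = InsertionCallSet("a")
        with pytest.warns(UserWarning):
            assert validate_against_assembly(empty, t["evidence"], {"chr1": t["donor"]}) is None

    def test_empty_alt_genome_rejected(self, two_insertion_toy):
        t = two_insertion_toy
        with pytest.raises(ValueError):
            validate_against_assembly(t["callset"], t["evidence"], {})
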