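"""Tandem and dispersed repeat detection in the control region."""

import numpy as np
import pytest

from mitochar import (
    GeneratorSpec,
    find_dispersed_repeats,
    find_tandem_repeats,
    generate,
    repeat_report,
)
from mitochar.model import AnnotatedMitogenome, GeneFeature
from mitochar.synthetic import generate_control_region


def naive_smallest_period(s):
    """Brute-force periodicity oracle: smallest p with s[i] == s[i % p]."""
    for p in range(1, len(s) + 1):
        if all(s[i] == s[i % p] for i in range(len(s))):
            return p
    return len(s)


def random_aperiodic_unit(rng, length):
    while True:
        u = "".join(rng.choice(list("ACGT"), size=length))
        if naive_smallest_period(u) == length:
            return u


class TestTandemFinder:
    def test_exact_short_unit(self):
        calls = find_tandem_repeats("ACGT" * 5, min_unit=4)
        assert len(calls) == 1
        r = calls[0]
        assert (r.start, r.unit_length, r.copy_number) == (0, 4, 5.0)
        assert r.mean_identity == 1.0 and r.consensus_unit == "ACGT"

    def test_random_sequence_is_empty_at_strict_settings(self):
        rng = np.random.default_rng(123)
        seq = "".join(rng.choice(list("ACGT"), size=1000))
        assert find_tandem_repeats(seq, min_unit=20, min_copies=3,
                                   min_identity=1.0) == []

    def test_random_sequence_is_empty_at_default_settings(self):
        rng = np.random.default_rng(124)
        for _ in range(5):
            seq = "".join(rng.choice(list("ACGT"), size=1000))
            assert find_tandem_repeats(seq) == []

    def test_degenerate_parameters_rejected(self):
        with pytest.raises(ValueError):
            find_tandem_repeats("ACGTACGT", min_unit=50, max_unit=10)

    def test_pure_power_sequences_match_periodicity_oracle(self):
        """On u^k inputs the reported unit equals the primitive period and
        the copy number equals k, across unit lengths and copy counts."""
        rng = np.random.default_rng(7)
        for ulen in range(3, 13):
            for k in (2, 3, 5, 8):
                unit = random_aperiodic_unit(rng, ulen)
                seq = unit * k
                calls = find_tandem_repeats(seq, min_unit=2,
                                            max_unit=len(seq) // 2,
                                            min_identity=1.0, alpha=1.0)
                assert calls, f"missed {ulen}x{k}"
                r = calls[0]
                assert r.unit_length == naive_smallest_period(seq[:ulen]) == ulen
                assert round(r.copy_number) == k and r.start == 0

    def test_planted_repeat_in_at_rich_background(self):
        seq, truth = generate_control_region(21, 1500, repeats=((48, 5.0, 1.0),))
        planted = truth["tandem"][0]
        calls = find_tandem_repeats(seq)
        hit = [r for r in calls if r.unit_length == 48]
        assert hit and round(hit[0].copy_number) == 5
        assert abs(hit[0].start - planted["start"]) <= 48

    def test_degraded_copies_still_detected(self):
        # with 5% per-copy degradation the array must still be found; the
        # reported unit may be a multiple of the planted one when adjacent
        # copies share correlated differences
        seq, truth = generate_control_region(22, 1500, repeats=((60, 6.0, 0.95),))
        planted = truth["tandem"][0]
        calls = find_tandem_repeats(seq)
        hit = [r for r in calls if r.unit_length % 60 == 0
               and abs(r.start - planted["start"]) <= r.unit_length]
        assert hit and hit[0].mean_identity >= 0.85
        assert hit[0].span >= 4 * 60  # most of the planted array covered

    def test_fractional_trailing_copy_reported(self):
        unit = "ACGTTGCAAT"  # aperiodic 10-mer
        seq = unit * 3 + unit[:5]
        calls = find_tandem_repeats(seq, min_unit=5, alpha=1.0)
        assert calls and calls[0].copy_number == pytest.approx(3.5, abs=0.1)

    def test_calls_are_within_bounds_and_non_overlapping(self):
        seq, _ = generate_control_region(
            33, 2400, repeats=((30, 4.0, 1.0), (75, 3.0, 1.0)))
        calls = find_tandem_repeats(seq)
        spans = sorted((r.start, r.start + r.span) for r in calls)
        assert all(0 <= s < e <= len(seq) for s, e in spans)
        assert all(spans[i][1] <= spans[i + 1][0] for i in range(len(spans) - 1))

    def test_reversed_sequence_mirrors_coordinates(self):
        seq, _ = generate_control_region(44, 1200, repeats=((40, 4.0, 1.0),))
        fwd = find_tandem_repeats(seq)
        rev = find_tandem_repeats(seq[::-1])
        assert {(r.unit_length, round(r.copy_number)) for r in fwd} == \
               {(r.unit_length, round(r.copy_number)) for r in rev}
        n = len(seq)
        assert {(n - (r.start + r.span), r.unit_length) for r in fwd} == \
               {(r.start, r.unit_length) for r in rev}


class TestDispersedFinder:
    def test_planted_distant_duplicate(self):
        rng = np.random.default_rng(9)
        bg = rng.choice(list("ACGT"), size=600)
        copy = "".join(rng.choice(list("ACGT"), size=60))
        seq = "".join(bg[:150]) + copy + "".join(bg[150:350]) + copy + "".join(bg[350:])
        pairs = find_dispersed_repeats(seq, min_length=50)
        assert len(pairs) == 1
        p = pairs[0]
        assert p.length >= 60 - 2 and p.pos2 - p.pos1 > p.length

    def test_tandem_array_is_not_dispersed(self):
        assert find_dispersed_repeats("ACGTACGTTTAA" * 30, min_length=20) == []

    def test_planted_172bp_pair_recovered(self):
        seq, truth = generate_control_region(5, 2238, dispersed=((172, 300),))
        planted = truth["dispersed"][0]
        pairs = find_dispersed_repeats(seq)
        assert len(pairs) == 1
        p = pairs[0]
        assert abs(p.pos1 - planted["pos1"]) <= 12
        assert abs(p.length - 172) <= 12
        assert p.pos2 - p.pos1 == planted["pos2"] - planted["pos1"]

    def test_short_sequence_returns_empty(self):
        assert find_dispersed_repeats("ACGT", min_length=50) == []


class TestRepeatReport:
    def test_planted_tandem_recovered_from_genome(self, genome, truth):
        report = repeat_report(genome)
        assert report.cr_present
        planted = truth.cr_tandem[0]
        hit = [r for r in report.tandem if r.unit_length == planted["unit_length"]]
        assert hit and round(hit[0].copy_number) == round(planted["copies"])
        assert hit[0].start == planted["start"]

    def test_tandem_and_dispersed_together(self):
        spec = GeneratorSpec(seed=9, cr_length=2600, cr_repeats=((32, 6.0, 1.0),),
                             cr_dispersed=((172, 300),))
        g, t = generate(spec)
        report = repeat_report(g)
        assert any(r.unit_length == 32 and round(r.copy_number) == 6
                   for r in report.tandem)
        assert len(report.dispersed) == 1
        assert report.dispersed[0].pos2 - report.dispersed[0].pos1 == \
            t.cr_dispersed[0]["pos2"] - t.cr_dispersed[0]["pos1"]

    def test_missing_cr_marker(self):
        g = AnnotatedMitogenome("X", "ACGT" * 30,
                                features=[GeneFeature("COX1", 0, 30, "J", "PCG")])
        report = repeat_report(g)
        assert not report.cr_present and report.tandem == ()
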