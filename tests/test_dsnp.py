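"""Deleterious-SNP identification: tallies and the filter cascade."""

import pytest
from hypothesis import given, settings, strategies as st

from burdenscan.dsnp import (
    LOF_CLASSES,
    identify_dsnps,
    per_chromosome_counts,
    tally_consequences,
    tally_sift,
)
from burdenscan.variant_io import AnnotationRecord, ConstraintTrack


def _rec(chrom="1H", pos=1, alt="G", consequence="missense_variant", canonical=True,
         sift=None, transcript="T.1"):
    cls = "deleterious" if sift is not None and sift <= 0.05 else (
        "tolerated" if sift is not None else None)
    return AnnotationRecord(
        locus_key=(chrom, pos, alt),
        transcript_id=transcript,
        consequence=consequence,
        canonical=canonical,
        sift_class=cls,
        sift_score=sift,
    )


class TestTallies:
    def test_empty_input_gives_all_zero(self):
        tally = tally_consequences([])
        assert tally.total == 0 and tally.lof_total == 0

    def test_lof_total_sums_the_seven_classes(self):
        records = [
            _rec(pos=i + 1, consequence=c, sift=None)
            for i, c in enumerate(LOF_CLASSES)
        ] + [_rec(pos=100, consequence="synonymous_variant")]
        tally = tally_consequences(records)
        assert tally.lof_total == 7
        assert tally.total == 8

    def test_per_snp_collapses_to_most_severe(self):
        # same locus annotated missense on one transcript, intron on another:
        # per-annotation counts both, per-SNP keeps the missense only
        records = [
            _rec(pos=1, consequence="missense_variant", sift=0.2, transcript="T.1"),
            _rec(pos=1, consequence="intron_variant", transcript="T.2"),
        ]
        per_row = tally_consequences(records, per_snp=False)
        per_snp = tally_consequences(records, per_snp=True)
        assert per_row.total == 2
        assert per_snp.total == 1
        assert per_snp.counts["missense_variant"] == 1

    def test_sift_tally_counts_classes_and_total(self):
        records = [_rec(pos=i + 1, sift=0.01) for i in range(2)] + [
            AnnotationRecord(("1H", 50 + i, "G"), "T.1", "missense_variant", True,
                             "tolerated_low_confidence", 0.4)
            for i in range(3)
        ]
        counts = tally_sift(records)
        assert counts["deleterious"] == 2
        assert counts["tolerated_low_confidence"] == 3
        assert counts["total"] == 5


FIVE_SNP_TRACK = ConstraintTrack({
    ("1H", 1): 1.2, ("1H", 2): 2.0, ("1H", 3): -0.5, ("1H", 4): 1.0, ("1H", 5): 3.0,
})

FIVE_SNP_RECORDS = [
    _rec(pos=1, sift=0.01),                       # qualifies on every predicate
    _rec(pos=2, sift=0.2),                        # fails SIFT
    _rec(pos=3, sift=0.01),                       # fails RS (negative)
    _rec(pos=4, sift=0.01, canonical=False),      # fails canonical
    _rec(pos=5, consequence="synonymous_variant"),  # fails consequence
]


class TestIdentify:
    def test_truth_table_fixture_keeps_exactly_one(self):
        dset = identify_dsnps(FIVE_SNP_RECORDS, FIVE_SNP_TRACK)
        assert dset.L == 1
        assert dset.keys() == [("1H", 1, "G")]

    def test_all_pass_when_thresholds_are_loose(self):
        dset = identify_dsnps(FIVE_SNP_RECORDS, FIVE_SNP_TRACK,
                              sift_max=1.0, rs_min=-10.0, canonical_only=False)
        missense = [r for r in FIVE_SNP_RECORDS if r.consequence == "missense_variant"]
        assert dset.L == len(missense)

    def test_rs_exactly_zero_is_excluded(self):
        track = ConstraintTrack({("1H", 1): 0.0})
        assert identify_dsnps([_rec(pos=1, sift=0.01)], track).L == 0

    def test_sift_threshold_inclusive_by_default_strict_on_request(self):
        track = ConstraintTrack({("1H", 1): 1.0})
        rec = _rec(pos=1, sift=0.05)
        assert identify_dsnps([rec], track).L == 1
        assert identify_dsnps([rec], track, sift_strict=True).L == 0

    def test_position_absent_from_track_fails_rs_criterion(self):
        assert identify_dsnps([_rec(pos=99, sift=0.01)], ConstraintTrack()).L == 0

    def test_empty_annotations_give_empty_set(self):
        assert identify_dsnps([], FIVE_SNP_TRACK).L == 0

    def test_per_chromosome_counts_conserve_total(self):
        track = ConstraintTrack({("1H", 1): 1.0, ("1H", 2): 1.0, ("2H", 3): 1.0})
        recs = [_rec(chrom=c, pos=p, sift=0.01)
                for c, p in [("1H", 1), ("1H", 2), ("2H", 3)]]
        dset = identify_dsnps(recs, track)
        counts = per_chromosome_counts(dset)
        assert counts == {"1H": 2, "2H": 1}
        assert sum(counts.values()) == dset.L


# -- randomized oracle: brute-force predicate evaluation ---------------------

consequences = st.sampled_from(
    ["missense_variant", "synonymous_variant", "intron_variant", "stop_gained"]
)


@st.composite
def annotation_tables(draw):
    n = draw(st.integers(0, 100))
    records, rs = [], {}
    for i in range(n):
        pos = draw(st.integers(1, 30))
        has_sift = draw(st.booleans())
        sift = draw(st.floats(0, 1, allow_nan=False)) if has_sift else None
        records.append(_rec(pos=pos, consequence=draw(consequences),
                            canonical=draw(st.booleans()), sift=sift,
                            transcript=f"T.{i}"))
        if draw(st.booleans()):
            rs[("1H", pos)] = draw(st.floats(-3, 5, allow_nan=False))
    return records, ConstraintTrack(rs)


def _brute_force_keys(records, track, sift_max, rs_min, canonical_only, strict):
    keys = set()
    for r in records:
        if r.consequence != "missense_variant":
            continue
        if canonical_only and not r.canonical:
            continue
        if r.sift_score is None:
            continue
        ok_sift = r.sift_score < sift_max if strict else r.sift_score <= sift_max
        rs = track.get(r.locus_key[0], r.locus_key[1])
        if ok_sift and rs is not None and rs > rs_min:
            keys.add(r.locus_key)
    return keys


@settings(max_examples=150, deadline=None, derandomize=True)
@given(table=annotation_tables(), sift_max=st.floats(0, 1), rs_min=st.floats(-1, 2),
       canonical_only=st.booleans(), strict=st.booleans())
def test_identify_matches_bruteforce_predicate(table, sift_max, rs_min, canonical_only, strict):
    records, track = table
    dset = identify_dsnps(records, track, sift_max=sift_max, rs_min=rs_min,
                          canonical_only=canonical_only, sift_strict=strict)
    assert set(dset.keys()) == _brute_force_keys(
        records, track, sift_max, rs_min, canonical_only, strict)


@settings(max_examples=60, deadline=None, derandomize=True)
@given(table=annotation_tables(),
       loose=st.floats(0.2, 1), tight=st.floats(0, 0.2),
       rs_lo=st.floats(-1, 0), rs_hi=st.floats(0, 2))
def test_tightening_thresholds_never_grows_the_set(table, loose, tight, rs_lo, rs_hi):
    records, track = table
    big = identify_dsnps(records, track, sift_max=loose, rs_min=rs_lo)
    small = identify_dsnps(records, track, sift_max=tight, rs_min=rs_hi)
    assert set(small.keys()) <= set(big.keys())
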