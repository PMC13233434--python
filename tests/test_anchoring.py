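"""Anchor detection in both coordinate spaces; padded symmetric expansion."""

import re

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from robfold.anchoring import (
    MotifPattern,
    build_expansion_sets,
    expand_window,
    filter_representative,
    find_anchors,
)
from robfold.structure_io import ProteinRecord


def _record(seq, start=1, coords=True):
    n = len(seq)
    return ProteinRecord(
        id="rec",
        sequence=seq,
        residue_numbers=list(range(start, start + n)),
        ca_coords=np.arange(3 * n, dtype=float).reshape(n, 3) if coords else None,
    )


class TestMotifPattern:
    def test_shorthand_x_compiles_to_any_residue(self):
        pat = MotifPattern.from_motif("CXXC")
        assert pat.regex == "C..C"
        assert pat.length == 4

    def test_variable_length_regex_rejected(self):
        with pytest.raises(ValueError):
            MotifPattern(name="bad", regex="C.*C")

    def test_invalid_regex_rejected(self):
        with pytest.raises(ValueError):
            MotifPattern(name="bad", regex="C[")

    def test_fixed_repetition_and_class_lengths(self):
        assert MotifPattern(name="p", regex="C.{2}C").length == 4
        assert MotifPattern(name="q", regex="[ED][ED]VD").length == 4


class TestFindAnchors:
    def test_no_match_returns_empty(self, cxxc):
        assert find_anchors(_record("AAAA"), cxxc) == []

    def test_overlapping_scan_finds_both_adjacent_sites(self, cxxc):
        rec = _record("CCACC")
        spans = [(s.seq_start, s.seq_end) for s in find_anchors(rec, cxxc, overlapping=True)]
        # oracle: enumerate all substrings of length 4 against the pattern
        expected = [
            (i, i + 4) for i in range(2) if re.fullmatch("C..C", rec.sequence[i : i + 4])
        ]
        assert spans == expected == [(0, 4), (1, 5)]
        spans_plain = [(s.seq_start, s.seq_end) for s in find_anchors(rec, cxxc, overlapping=False)]
        assert spans_plain == [(0, 4)]

    def test_author_coordinates_follow_non_contiguous_numbering(self, cxxc):
        # crystal-like numbering: the chain starts at author residue 22, so a
        # match at sequence index 39 sits at author residues 61-64
        seq = list("A" * 400)
        for idx in (39, 384):
            seq[idx : idx + 4] = list("CGHC")
        rec = _record("".join(seq), start=22)
        sites = find_anchors(rec, cxxc)
        assert [(s.res_start, s.res_end) for s in sites] == [(61, 64), (406, 409)]
        for s in sites:
            assert s.res_start == rec.residue_numbers[s.seq_start]

    def test_every_site_is_a_regex_match(self, pdi_like, cxxc):
        _, records, _ = pdi_like
        for rec in records:
            for s in find_anchors(rec, cxxc):
                assert re.fullmatch(cxxc.regex, rec.sequence[s.seq_start : s.seq_end])
                assert s.matched == rec.sequence[s.seq_start : s.seq_end]


class TestExpandWindow:
    def test_window_length_is_motif_plus_two_radii(self, cxxc):
        rec = _record("A" * 100 + "CGHC" + "A" * 100)
        (site,) = find_anchors(rec, cxxc)
        w = expand_window(rec, site, 10)
        assert w.window_length == 24
        assert w.padded_seq[10:14] == "CGHC"
        assert not w.pad_mask.any() and w.coord_complete

    def test_leading_padding_when_anchor_near_n_terminus(self, cxxc):
        rec = _record("AAA" + "CGHC" + "A" * 50)
        (site,) = find_anchors(rec, cxxc)
        w = expand_window(rec, site, 10)
        assert w.padded_seq[:7] == "X" * 7
        assert w.pad_mask[:7].all() and not w.pad_mask[7:].any()
        assert not w.coord_complete

    def test_radius_zero_is_the_bare_motif(self, cxxc):
        rec = _record("AACGHCAA")
        (site,) = find_anchors(rec, cxxc)
        w = expand_window(rec, site, 0)
        assert w.padded_seq == site.matched
        assert w.coord_complete

    def test_missing_ca_breaks_coord_completeness(self, cxxc):
        rec = _record("A" * 20 + "CGHC" + "A" * 20)
        rec.ca_coords[5] = np.nan
        (site,) = find_anchors(rec, cxxc)
        assert expand_window(rec, site, 10).coord_complete  # index 5 outside window
        assert not expand_window(rec, site, 20).coord_complete

    @given(pos=st.integers(0, 96), radius=st.integers(0, 120))
    @settings(max_examples=60, deadline=None)
    def test_padding_count_matches_bounds_formula(self, pos, radius):
        seq = "A" * pos + "CGHC" + "A" * (96 - pos)
        rec = _record(seq)
        pat = MotifPattern(name="CXXC", regex="C..C")
        site = next(s for s in find_anchors(rec, pat) if s.seq_start == pos)
        w = expand_window(rec, site, radius)
        expected = max(0, radius - pos) + max(0, (pos + 4 + radius) - len(seq))
        assert int(w.pad_mask.sum()) == expected


class TestExpansionSets:
    def test_one_window_per_site_per_length(self, pdi_like, cxxc):
        _, records, truth = pdi_like
        groups = build_expansion_sets(records, cxxc, radii=[10, 20])
        assert set(groups) == {24, 44}
        assert all(len(ws) == len(truth.sites) for ws in groups.values())

    def test_zero_anchor_family_yields_empty_map(self, cxxc):
        rec = _record("AAAAAAAA")
        assert build_expansion_sets([rec], cxxc, radii=[10]) == {}

    def test_deterministic_ordering(self, pdi_like, cxxc):
        _, records, _ = pdi_like
        a = build_expansion_sets(records, cxxc, radii=[10])
        b = build_expansion_sets(records, cxxc, radii=[10])
        assert [w.window_id for w in a[24]] == [w.window_id for w in b[24]]


class TestRepresentativenessFilter:
    def _groups(self, cxxc):
        long_rec = _record("A" * 60 + "CGHC" + "A" * 60)
        long_rec.id = "long"
        short_rec = _record("A" * 6 + "CGHC" + "A" * 6)
        short_rec.id = "short"
        return build_expansion_sets([long_rec, short_rec], cxxc, radii=[5, 40])

    def test_category_dropped_when_subgroup_loses_coverage(self, cxxc):
        groups = self._groups(cxxc)
        gmap = {"long": "metazoa", "short": "fungi"}
        kept = filter_representative(groups, gmap)
        assert set(kept) == {14}  # radius 40 pads the short protein -> dropped

    def test_single_subgroup_never_dropped(self, cxxc):
        groups = self._groups(cxxc)
        gmap = {"long": "all", "short": "all"}
        # 'long' alone keeps every length complete, so every category survives
        assert set(filter_representative(groups, gmap)) == {14, 84}

    def test_sequence_level_analyses_keep_all_categories(self, cxxc):
        groups = self._groups(cxxc)
        gmap = {"long": "metazoa", "short": "fungi"}
        assert set(filter_representative(groups, gmap, require_coords=False)) == {14, 84}

    def test_missing_group_label_raises(self, cxxc):
        groups = self._groups(cxxc)
        with pytest.raises(KeyError):
            filter_representative(groups, {"long": "metazoa"})
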