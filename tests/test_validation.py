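"""Null-model control, IoU site benchmark and the PROSITE compiler."""

import re
from collections import Counter

import numpy as np
import pandas as pd
import pytest
from helpers import optimal_tp_count

from robfold.anchoring import MotifPattern, find_anchors
from robfold.structure_io import ProteinRecord
from robfold.validation import (
    compile_prosite,
    interval_iou,
    match_sites_iou,
    micro_average,
    null_decay_experiment,
    sample_null_anchors,
    scan_prosite,
    terminal_margins,
)


@pytest.fixture(scope="module")
def family_with_sites(request):
    pdi = request.getfixturevalue("pdi_like")
    _, records, truth = pdi
    return records, truth.sites


class TestNullSampling:
    def test_permuted_motif_preserves_composition(self, family_with_sites):
        records, sites = family_with_sites
        trials = sample_null_anchors(records, sites, n=50, seed=3)
        assert len(trials) == 50
        motif = sites[0].matched
        for t in trials:
            assert Counter(t.permuted_motif) == Counter(motif)

    def test_identity_permutation_rejected_when_possible(self, family_with_sites):
        records, sites = family_with_sites
        trials = sample_null_anchors(records, sites, n=50, seed=3)
        assert all(t.permuted_motif != sites[0].matched for t in trials)

    def test_positions_respect_terminal_margins(self, family_with_sites):
        records, sites = family_with_sites
        n_margin, c_margin = terminal_margins(records, sites)
        m = len(sites[0].matched)
        lengths = {r.id: len(r) for r in records}
        # margin and composition invariants over a large trial batch
        for t in sample_null_anchors(records, sites, n=1000, seed=5):
            for pid, start in t.positions.items():
                assert start >= n_margin
                assert lengths[pid] - (start + m) >= c_margin

    def test_reproducible_under_seed(self, family_with_sites):
        records, sites = family_with_sites
        a = sample_null_anchors(records, sites, n=10, seed=42)
        b = sample_null_anchors(records, sites, n=10, seed=42)
        assert [(t.permuted_motif, t.positions) for t in a] == [
            (t.permuted_motif, t.positions) for t in b
        ]
        c = sample_null_anchors(records, sites, n=10, seed=43)
        assert [t.positions for t in a] != [t.positions for t in c]

    def test_record_without_admissible_position_is_skipped(self, cxxc):
        long_rec = ProteinRecord(id="long", sequence="A" * 200 + "CGHC" + "A" * 200,
                                 residue_numbers=list(range(1, 405)))
        short_rec = ProteinRecord(id="short", sequence="A" * 10 + "CGHC" + "A" * 10,
                                  residue_numbers=list(range(1, 25)))
        sites = find_anchors(long_rec, cxxc) + find_anchors(short_rec, cxxc)
        # margins come from the short protein (10 each side); the long record
        # always admits positions, the short one exactly its biological start
        trials = sample_null_anchors([long_rec, short_rec], sites, n=5, seed=1)
        for t in trials:
            assert t.positions["short"] == 10


class TestNullDecay:
    def test_biological_curve_dominates_null_mean_over_core(self, family_with_sites):
        records, sites = family_with_sites
        res = null_decay_experiment(records, sites, n=20, seed=8, radii=range(10, 101, 10))
        merged = res.biological.merge(res.envelope, on="window_length")
        core_extent = merged["window_length"] <= 44  # planted core: motif + 20 per side
        assert (merged.loc[core_extent, "mean_si"] >= merged.loc[core_extent, "null_mean"]).all()

    def test_no_conservation_family_shows_no_separation(self):
        from robfold.synthetic import FamilySpec, generate_family

        spec = FamilySpec(core_rate=0.95, flank_rate=0.95, core_radius=0, seed=17)
        records, truth = generate_family(spec)
        res = null_decay_experiment(records, truth.sites, n=20, seed=8, radii=[30, 60])
        merged = res.biological.merge(res.envelope, on="window_length")
        # without planted conservation the biological curve collapses onto the
        # null level once the forced-anchor contribution (the motif's m
        # identical positions, worth 100*m/L points) is discounted
        forced = 100.0 * 4 / merged["window_length"]
        gap = merged["mean_si"] - merged["null_mean"]
        assert (gap <= forced + 2.0).all()

    def test_degenerate_trial_at_biological_positions_reproduces_curve(self, cxxc):
        from robfold.synthetic import FamilySpec, generate_family
        from robfold.validation import _windows_at_positions
        from robfold.fold_one import conservation_curve

        spec = FamilySpec(n_proteins=5, anchors_per_protein=1, seed=23)
        records, truth = generate_family(spec)
        positions = {s.protein_id: s.seq_start for s in truth.sites}
        groups = _windows_at_positions(records, positions, 4, [10, 20])
        null_curve = conservation_curve(groups)
        res = null_decay_experiment(records, truth.sites, n=2, seed=1, radii=[10, 20])
        pd.testing.assert_frame_equal(null_curve, res.biological)


class TestIoUMatching:
    def test_identical_sets_are_perfect(self):
        sites = [("p1", 61, 64), ("p1", 406, 409), ("p2", 33, 36)]
        r = match_sites_iou(sites, list(sites))
        assert (r.tp, r.fp, r.fn) == (3, 0, 0)
        assert r.precision == r.recall == r.f1 == 1.0
        assert r.mean_iou == 1.0

    def test_partial_overlap_below_threshold(self):
        # [10,14] vs [12,16]: intersection 3, union 7 -> IoU 3/7 < 0.5
        assert interval_iou((10, 14), (12, 16)) == pytest.approx(3 / 7)
        r = match_sites_iou([("p", 10, 14)], [("p", 12, 16)], iou_min=0.5)
        assert (r.tp, r.fp, r.fn) == (0, 1, 1)

    def test_empty_prediction_all_false_negatives(self):
        r = match_sites_iou([], [("p", 1, 4)] * 4)
        assert (r.tp, r.fn, r.recall) == (0, 4, 0.0)
        assert r.precision == 1.0  # degenerate, logged

    def test_malformed_interval_rejected(self):
        with pytest.raises(ValueError):
            match_sites_iou([("p", 5, 3)], [("p", 5, 3)])

    def test_cross_protein_intervals_never_match(self):
        r = match_sites_iou([("p1", 1, 4)], [("p2", 1, 4)])
        assert (r.tp, r.fp, r.fn) == (0, 1, 1)

    def test_matcher_attains_exhaustive_optimum(self, rng):
        # the matcher's TP count equals brute-force optimal one-to-one
        # matching on random instances with <= 6 intervals per side
        for _ in range(150):
            n_p, n_r = rng.integers(0, 7), rng.integers(0, 7)
            pred = [("p", int(s), int(s + rng.integers(3, 8))) for s in rng.integers(0, 40, n_p)]
            ref = [("p", int(s), int(s + rng.integers(3, 8))) for s in rng.integers(0, 40, n_r)]
            tp = match_sites_iou(pred, ref, iou_min=0.5).tp
            assert tp == optimal_tp_count(pred, ref, iou_min=0.5)


class TestMicroAverage:
    def test_pooled_perfect_motifs(self):
        per = [
            match_sites_iou([("p", 1, 4)] , [("p", 1, 4)], motif="CXXC"),
            match_sites_iou([("q", 9, 12)], [("q", 9, 12)], motif="EEVD"),
        ]
        micro = micro_average(per)
        assert micro.tp == 2 and micro.f1 == 1.0

    def test_pooled_recall_lies_between_motif_recalls(self):
        perfect = match_sites_iou([("p", 1, 4)], [("p", 1, 4)])
        misses = match_sites_iou([], [("q", 1, 4), ("q", 9, 12)])
        micro = micro_average([perfect, misses])
        assert misses.recall < micro.recall < perfect.recall

    def test_single_motif_micro_is_identity(self):
        r = match_sites_iou([("p", 1, 4)], [("p", 2, 5)], iou_min=0.5)
        micro = micro_average([r])
        assert (micro.tp, micro.fp, micro.fn) == (r.tp, r.fp, r.fn)
        assert micro.precision == r.precision and micro.recall == r.recall


class TestPrositeCompiler:
    @pytest.mark.parametrize(
        "pattern,regex",
        [
            ("C-x(2)-C", "C.{2}C"),
            ("E-E-V-D", "EEVD"),
            ("[ND]-x-T", "[ND].T"),
            ("{P}-x(1,3)-C", "[^P].{1,3}C"),
            ("<M-x>", "^M.$"),
            ("C-G-H-C.", "CGHC"),
        ],
    )
    def test_compilation(self, pattern, regex):
        assert compile_prosite(pattern) == regex

    def test_unsupported_token_rejected(self):
        with pytest.raises(ValueError):
            compile_prosite("C-x(*)-C")

    def test_scan_agrees_with_motif_regex_scan(self, pdi_like, cxxc):
        _, records, truth = pdi_like
        hits = scan_prosite(records, "C-x(2)-C")
        predicted = [
            (s.protein_id, s.res_start, s.res_end)
            for rec in records
            for s in find_anchors(rec, cxxc)
        ]
        assert sorted(hits) == sorted(predicted)
        assert len(hits) == len(truth.sites)
        r = match_sites_iou(predicted, hits, iou_min=0.5, motif="CXXC")
        assert r.f1 == 1.0 and r.mean_iou == 1.0

    def test_scan_reports_author_numbering(self):
        rec = ProteinRecord(id="x", sequence="AACGHCAA", residue_numbers=list(range(22, 30)))
        assert scan_prosite([rec], "C-x(2)-C") == [("x", 24, 27)]
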