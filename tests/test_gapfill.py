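"""Anchor finding, patch planning, splicing and coordinate liftover."""

import numpy as np
import pytest

from gapmend.alignment import AlignmentRecord
from gapmend.gapfill import (
    FillConfig,
    apply_patches,
    fill_gaps,
    find_anchors,
    liftover,
    plan_patch,
    reverse_complement,
)
from gapmend.genome_io import GapRecord, SequenceRecord, find_gaps
from gapmend import simulate


def _aln(tname, tstart, tend, qname="d", qstart=None, qend=None, strand="+", score=None):
    if qstart is None:
        qstart, qend = tstart, tend
    return AlignmentRecord(
        qname=qname, qstart=qstart, qend=qend, strand=strand,
        tname=tname, tstart=tstart, tend=tend,
        matches=tend - tstart, block_len=tend - tstart, score=score,
    )


class TestFindAnchors:
    GAP = GapRecord("c", 50, 60)

    def test_left_anchor_adjacent(self):
        left, right = find_anchors(self.GAP, [_aln("c", 0, 50)], 100, 10)
        assert len(left) == 1 and not right
        assert left[0].distance_to_gap == 0
        assert left[0].donor_inner == 50

    def test_right_anchor_with_distance(self):
        left, right = find_anchors(self.GAP, [_aln("c", 200, 300)], 200, 10)
        assert not left and len(right) == 1
        assert right[0].distance_to_gap == 140

    def test_outside_window_excluded(self):
        # alignment ends 150 bp before the gap, window only 100
        left, right = find_anchors(GapRecord("c", 200, 210), [_aln("c", 0, 50)], 100, 10)
        assert not left and not right

    def test_spanning_alignment_in_both_lists(self):
        left, right = find_anchors(self.GAP, [_aln("c", 0, 200)], 100, 10)
        assert len(left) == len(right) == 1
        assert left[0].spanning and right[0].spanning
        assert left[0].donor_inner == 50 and right[0].donor_inner == 60

    def test_minus_strand_donor_inner(self):
        # '-' strand: target tend corresponds to donor qstart
        aln = _aln("c", 0, 50, qstart=100, qend=150, strand="-")
        left, _ = find_anchors(self.GAP, [aln], 100, 10)
        assert left[0].donor_inner == 100

    def test_min_anchor_len_respected(self):
        left, right = find_anchors(self.GAP, [_aln("c", 40, 50)], 100, 20)
        assert not left and not right


class TestPlanPatch:
    def test_paired_plan_round_trip_geometry(self):
        # truth = A(50) + X(10) + B(50); target has Ns for X; donor is truth
        gap = GapRecord("c", 50, 60)
        left = _aln("c", 0, 50)
        right = _aln("c", 60, 110)
        l, r = find_anchors(gap, [left, right], 100, 10)
        plan = plan_patch(gap, l, r)
        assert plan.status == "planned" and plan.mode == "paired"
        assert plan.donor_interval == (50, 60)
        assert plan.orientation == "+"

    def test_missing_side_statuses(self):
        gap = GapRecord("c", 50, 60)
        l, r = find_anchors(gap, [_aln("c", 0, 50)], 100, 10)
        assert plan_patch(gap, l, r).status == "no_right_anchor"
        l, r = find_anchors(gap, [_aln("c", 60, 110)], 100, 10)
        assert plan_patch(gap, l, r).status == "no_left_anchor"

    def test_discordant_donors(self):
        gap = GapRecord("c", 50, 60)
        l, r = find_anchors(
            gap,
            [_aln("c", 0, 50, qname="d1"), _aln("c", 60, 110, qname="d2")],
            100, 10,
        )
        assert plan_patch(gap, l, r).status == "discordant_anchors"

    def test_span_too_long(self):
        gap = GapRecord("c", 50, 60)
        l, r = find_anchors(
            gap,
            [_aln("c", 0, 50, qstart=0, qend=50),
             _aln("c", 60, 110, qstart=9000, qend=9050)],
            100, 10,
        )
        assert plan_patch(gap, l, r, max_patch_len=1000).status == "span_too_long"

    def test_spanning_preferred_over_pair(self):
        gap = GapRecord("c", 50, 60)
        alns = [_aln("c", 0, 50), _aln("c", 60, 110), _aln("c", 0, 110, qname="span")]
        l, r = find_anchors(gap, alns, 100, 10)
        plan = plan_patch(gap, l, r)
        assert plan.mode == "spanning" and plan.donor_name == "span"
        assert plan.donor_interval == (50, 60)

    def test_negative_donor_span_trimmed(self):
        # donor anchors overlap into the flank by 20 bp -> trims resolve it
        gap = GapRecord("c", 100, 110)
        l, r = find_anchors(
            gap,
            [_aln("c", 0, 100, qstart=0, qend=100),
             _aln("c", 110, 210, qstart=80, qend=180)],
            100, 10,
        )
        plan = plan_patch(gap, l, r, trim_cap=50)
        assert plan.status == "planned"
        assert plan.left_trim + plan.right_trim == 20
        assert plan.patch_len == 0

    def test_negative_donor_span_unresolvable(self):
        gap = GapRecord("c", 100, 110)
        l, r = find_anchors(
            gap,
            [_aln("c", 0, 100, qstart=0, qend=100),
             _aln("c", 110, 210, qstart=80, qend=180)],
            100, 10,
        )
        assert plan_patch(gap, l, r, trim_cap=5).status == "donor_overlap_unresolvable"


class TestApplyPatches:
    def test_truth_reconstruction_single_gap(self):
        a, x, b = "ACGTG" * 10, "TTTTACGTGA", "GATTC" * 10
        truth = a + x + b
        target = [SequenceRecord("c", a + "N" * 10 + b)]
        donor = [SequenceRecord("d", truth)]
        alns = [
            _aln("c", 0, 50, qname="d", qstart=0, qend=50),
            _aln("c", 60, 110, qname="d", qstart=60, qend=110),
        ]
        patched, lift, report, plans = fill_gaps(target, donor, alns, FillConfig(
            flank_window=100, min_anchor_len=10))
        assert patched[0].seq == truth
        assert report.gaps_filled == 1
        assert lift.patches["c"] == [(50, 60)]

    def test_empty_plan_list_is_identity(self):
        target = [SequenceRecord("c", "ACGTNNNNACGT")]
        patched, lift, report = apply_patches(target, [], [])
        assert patched[0].seq == target[0].seq
        assert lift.segments["c"] == [(0, 12, 0)]
        assert report.gaps_filled == 0

    def test_minus_orientation_patch_is_reverse_complement(self):
        gap = GapRecord("c", 4, 8)
        target = [SequenceRecord("c", "ACGT" + "NNNN" + "ACGT")]
        donor_core = "GGTA"
        donor = [SequenceRecord("d", "TTTT" + reverse_complement(donor_core) + "TTTT")]
        alns = [
            _aln("c", 0, 4, qname="d", qstart=8, qend=12, strand="-"),
            _aln("c", 8, 12, qname="d", qstart=0, qend=4, strand="-"),
        ]
        patched, _, report, plans = fill_gaps(target, donor, alns, FillConfig(
            flank_window=50, min_anchor_len=2))
        assert plans[0].orientation == "-"
        assert patched[0].seq == "ACGT" + donor_core + "ACGT"

    def test_patched_bases_uppercase_flank_case_preserved(self):
        target = [SequenceRecord("c", "acgt" + "NNNN" + "acgt")]
        donor = [SequenceRecord("d", "acgt" + "ttgg" + "acgt")]
        alns = [
            _aln("c", 0, 4, qname="d", qstart=0, qend=4),
            _aln("c", 8, 12, qname="d", qstart=8, qend=12),
        ]
        patched, _, _, _ = fill_gaps(target, donor, alns, FillConfig(
            flank_window=50, min_anchor_len=2))
        assert patched[0].seq == "acgt" + "TTGG" + "acgt"

    def test_colliding_patches_error(self):
        target = [SequenceRecord("c", "AC" + "NN" + "G" + "NN" + "CA")]
        donor = [SequenceRecord("d", "ACTTGTTCA")]
        gaps = find_gaps(target[0], 1)
        from gapmend.gapfill import PatchPlan
        plans = [
            PatchPlan(gaps[0], "planned", mode="paired", donor_name="d",
                      donor_interval=(2, 4), orientation="+", right_trim=2),
            PatchPlan(gaps[1], "planned", mode="paired", donor_name="d",
                      donor_interval=(5, 7), orientation="+"),
        ]
        with pytest.raises(ValueError, match="colliding"):
            apply_patches(target, donor, plans)


class TestLiftover:
    def _lift_for(self, seed=3):
        cfg = simulate.SimConfig(
            seed=seed, n_chroms=1, chrom_len=120_000, telomere_copies=100,
            centromere_array_len=15_000, n_gaps_per_chrom=3,
            gap_len_range=(100, 400), donor_frag_len_range=(30_000, 60_000),
            gap_margin=3_000, donor_divergence=0.0,
        )
        truth = simulate.simulate_genome(cfg)
        scaffold, gap_truth = simulate.degrade_to_scaffold(truth)
        donor, _, alns = simulate.make_donor(truth, gap_truth=gap_truth)
        patched, lift, report, _ = fill_gaps(scaffold, donor, alns)
        return scaffold, gap_truth, lift

    def test_positions_before_first_edit_unchanged(self):
        scaffold, gap_truth, lift = self._lift_for()
        first_gap = min(g.start for g in gap_truth)
        assert liftover(gap_truth[0].chrom, first_gap - 1, lift) == first_gap - 1
        assert liftover(gap_truth[0].chrom, 0, lift) == 0

    def test_removed_positions_report_deleted(self):
        scaffold, gap_truth, lift = self._lift_for()
        g = gap_truth[0]
        assert liftover(g.chrom, g.start, lift) is None
        assert liftover(g.chrom, g.end - 1, lift) is None

    def test_shift_arithmetic(self):
        # 10-N gap replaced by a 25-bp patch, no trims: downstream shifts +15
        target = [SequenceRecord("c", "A" * 100 + "N" * 10 + "G" * 100)]
        donor = [SequenceRecord("d", "A" * 100 + "C" * 25 + "G" * 100)]
        alns = [
            _aln("c", 0, 100, qname="d", qstart=0, qend=100),
            _aln("c", 110, 210, qname="d", qstart=125, qend=225),
        ]
        patched, lift, _, _ = fill_gaps(target, donor, alns, FillConfig(
            flank_window=500, min_anchor_len=10))
        assert patched[0].length == 225
        assert liftover("c", 150, lift) == 165

    def test_monotone_on_random_edit_scripts(self):
        rng = np.random.default_rng(42)
        for seed in range(5):
            scaffold, gap_truth, lift = self._lift_for(seed)
            chrom = scaffold[0].id
            n = scaffold[0].length
            pos = np.sort(rng.integers(0, n, size=200))
            lifted = [liftover(chrom, int(p), lift) for p in pos]
            kept = [(p, q) for p, q in zip(pos, lifted) if q is not None]
            for (p0, q0), (p1, q1) in zip(kept, kept[1:]):
                if p0 < p1:
                    assert q0 < q1

    def test_unknown_chromosome_is_error(self):
        _, _, lift = self._lift_for()
        with pytest.raises(KeyError):
            liftover("nope", 0, lift)


def test_idempotent_on_gap_free_assembly(small_truth, small_donor):
    donor, _, alns = small_donor
    patched, lift, report, plans = fill_gaps(small_truth.genome, donor, alns)
    assert report.gaps_found == 0
    assert plans == []
    assert [r.seq for r in patched] == [r.seq for r in small_truth.genome]


def test_length_bookkeeping_identity(small_truth, small_scaffold, small_donor):
    scaffold, gap_truth = small_scaffold
    donor, _, alns = small_donor
    patched, lift, report, plans = fill_gaps(scaffold, donor, alns)
    by_chrom = {r.id: r for r in scaffold}
    for rec in patched:
        old = by_chrom[rec.id]
        planned = [p for p in plans if p.planned and p.gap.chrom == rec.id]
        expected = old.length - sum(
            p.gap.length + p.left_trim + p.right_trim - p.patch_len for p in planned
        )
        assert rec.length == expected == lift.new_lengths[rec.id]
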