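import math

import numpy as np
import pysam
import pytest

from sagescore.csm_core import InstanceError, is_convex
from sagescore.flow_solver import solve_csm
from sagescore.instance_builder import (
    Placement,
    ReadPlacementSet,
    ScoringParams,
    build_instance,
    load_params,
    load_placements,
    pair_cost,
    segment_template,
)


class TestScoringParams:
    def test_defaults_match_reference_settings(self):
        p = ScoringParams()
        assert p.segment_length == 1000
        assert p.unmatched_penalty == 100.0
        assert p.discordant_penalty == 90.0
        assert p.coverage_cost_kind == "polynomial"
        assert p.coverage_exponent == 2.0
        assert p.mismatch_cost == 30.0
        assert p.max_mismatches_per_end == 3

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"segment_length": 0},
            {"unmatched_penalty": -1},
            {"coverage_cost_kind": "cubic"},
            {"coverage_exponent": 0.5},
            {"max_mismatches_per_end": -1},
        ],
    )
    def test_invalid_params_rejected(self, kwargs):
        with pytest.raises(ValueError):
            ScoringParams(**kwargs)

    def test_per_end_maximum_cost_is_90(self):
        p = ScoringParams()
        assert p.mismatch_cost * p.max_mismatches_per_end == 90.0
        # per-pair concordant range is therefore 0..180
        assert pair_cost(90.0, 90.0, True, p) == 180.0
        assert pair_cost(0.0, 0.0, True, p) == 0.0


class TestParamFile:
    def test_load_round_trip(self, tmp_path):
        cfg = tmp_path / "p.cfg"
        cfg.write_text(
            "segment_length = 500\n"
            "unmatched_penalty = 50\n"
            "coverage_cost_kind = linear\n"
            "# a comment\n"
            "mismatch_cost = 10\n"
        )
        p = load_params(str(cfg))
        assert p.segment_length == 500
        assert p.unmatched_penalty == 50.0
        assert p.coverage_cost_kind == "linear"
        assert p.mismatch_cost == 10.0

    def test_unknown_key_names_it(self, tmp_path):
        cfg = tmp_path / "p.cfg"
        cfg.write_text("bogus_setting = 1\n")
        with pytest.raises(ValueError, match="bogus_setting"):
            load_params(str(cfg))

    def test_expected_coverage_list(self, tmp_path):
        cfg = tmp_path / "p.cfg"
        cfg.write_text("expected_coverage = 10, 20, 5\n")
        assert load_params(str(cfg)).expected_coverage == (10.0, 20.0, 5.0)


class TestSegmentTemplate:
    def test_short_last_segment_scaled(self, default_params):
        seg = segment_template(2500, 50, default_params)
        assert seg.boundaries == ((0, 1000), (1000, 2000), (2000, 2500))
        assert seg.expected_coverage == (20.0, 20.0, 10.0)

    def test_zero_reads(self, default_params):
        seg = segment_template(1000, 0, default_params)
        assert len(seg) == 1
        assert seg.expected_coverage == (0.0,)

    def test_reference_scale(self, default_params):
        # 166 kb / ~24,900 reads: full segments expect coverage 150
        seg = segment_template(166000, 24900, default_params)
        assert len(seg) == 166
        assert seg.expected_coverage[0] == pytest.approx(150.0)

    def test_lambdas_sum_to_n_reads(self, default_params, rng):
        for _ in range(25):
            length = int(rng.integers(1, 10_000))
            n = int(rng.integers(0, 5000))
            seg = segment_template(length, n, default_params)
            assert sum(seg.expected_coverage) == pytest.approx(n)
            assert seg.boundaries[0][0] == 0
            assert seg.boundaries[-1][1] == length
            for (a, b), (c, d) in zip(seg.boundaries, seg.boundaries[1:]):
                assert b == c

    def test_nonpositive_length_rejected(self, default_params):
        with pytest.raises(ValueError):
            segment_template(0, 10, default_params)

    def test_override_validated(self, default_params):
        params = ScoringParams(expected_coverage=(5.0,))
        with pytest.raises(ValueError):
            segment_template(2500, 50, params)

    def test_segment_of_boundaries(self, default_params):
        seg = segment_template(2500, 0, default_params)
        assert seg.segment_of(0) == 0
        assert seg.segment_of(999) == 0
        assert seg.segment_of(1000) == 1
        assert seg.segment_of(2499) == 2
        with pytest.raises(InstanceError):
            seg.segment_of(2500)


class TestPairCost:
    def test_concordant_sums(self, default_params):
        assert pair_cost(30.0, 40.0, True, default_params) == 70.0

    def test_discordant_adds_penalty(self, default_params):
        assert pair_cost(30.0, None, False, default_params) == 120.0
        assert pair_cost(None, 25.0, False, default_params) == 115.0

    def test_identity_pair_is_free(self, default_params):
        assert pair_cost(0.0, 0.0, True, default_params) == 0.0

    def test_no_mapped_end_has_no_placement(self, default_params):
        assert pair_cost(None, None, False, default_params) is None

    def test_invalid_combinations_rejected(self, default_params):
        with pytest.raises(ValueError):
            pair_cost(10.0, None, True, default_params)
        with pytest.raises(ValueError):
            pair_cost(10.0, 10.0, False, default_params)
        with pytest.raises(ValueError):
            pair_cost(-1.0, 0.0, True, default_params)


class TestBuildInstance:
    def test_single_placement(self, default_params):
        seg = segment_template(2500, 1, default_params)
        ps = [ReadPlacementSet("r0", (Placement(2100, 5.0),))]
        inst = build_instance(ps, seg, default_params)
        assert dict(inst.matching_costs) == {("r0", "seg000002"): 5.0}
        assert inst.coverage_costs["r0"].costs == (100.0, 0.0)

    def test_per_segment_minimum_kept(self, default_params):
        seg = segment_template(2500, 1, default_params)
        ps = [ReadPlacementSet("r0", (Placement(10, 7.0), Placement(500, 3.0)))]
        inst = build_instance(ps, seg, default_params)
        assert dict(inst.matching_costs) == {("r0", "seg000000"): 3.0}

    def test_two_segments_capped_by_read_table(self, default_params):
        seg = segment_template(2500, 1, default_params)
        ps = [ReadPlacementSet("r0", (Placement(10, 0.0), Placement(1500, 0.0)))]
        inst = build_instance(ps, seg, default_params)
        assert len(inst.matching_costs) == 2
        m, _ = solve_csm(inst)
        assert len(m) <= 1  # w_c(x, 2) is infinite

    def test_placement_outside_template_rejected(self, default_params):
        seg = segment_template(2500, 1, default_params)
        ps = [ReadPlacementSet("r0", (Placement(9999, 0.0),))]
        with pytest.raises(InstanceError):
            build_instance(ps, seg, default_params)

    def test_start_position_decides_segment(self, default_params):
        # a placement starting just before a boundary belongs to that segment
        seg = segment_template(2500, 1, default_params)
        ps = [ReadPlacementSet("r0", (Placement(999, 1.0),))]
        inst = build_instance(ps, seg, default_params)
        assert ("r0", "seg000000") in inst.matching_costs

    def test_unplaced_reads_retained(self, default_params):
        seg = segment_template(1000, 2, default_params)
        ps = [
            ReadPlacementSet("r0", (Placement(5, 0.0),)),
            ReadPlacementSet("r1", ()),
        ]
        inst = build_instance(ps, seg, default_params)
        assert inst.X == ("r0", "r1")
        assert inst.d_x("r1") == 0

    def test_duplicate_read_ids_rejected(self, default_params):
        seg = segment_template(1000, 2, default_params)
        ps = [ReadPlacementSet("r0", ()), ReadPlacementSet("r0", ())]
        with pytest.raises(InstanceError):
            build_instance(ps, seg, default_params)

    @pytest.mark.parametrize("kind,exponent", [("polynomial", 2), ("polynomial", 3), ("linear", 1)])
    def test_generated_tables_are_convex(self, rng, kind, exponent):
        params = ScoringParams(coverage_cost_kind=kind, coverage_exponent=exponent)
        for _ in range(10):
            n = int(rng.integers(0, 200))
            seg = segment_template(3210, n, params)
            ps = [
                ReadPlacementSet(
                    f"r{i}", (Placement(int(rng.integers(0, 3210)), float(rng.integers(0, 180))),)
                )
                for i in range(n)
            ]
            inst = build_instance(ps, seg, params)
            for z in inst.X + inst.Y:
                assert is_convex(inst.coverage_costs[z])

    def test_order_invariance(self, default_params, rng):
        seg = segment_template(5000, 20, default_params)
        ps = [
            ReadPlacementSet(
                f"r{i:02d}",
                tuple(
                    Placement(int(rng.integers(0, 5000)), float(rng.integers(0, 180)))
                    for _ in range(int(rng.integers(0, 4)))
                ),
            )
            for i in range(20)
        ]
        inst1 = build_instance(ps, seg, default_params)
        shuffled = list(ps)[::-1]
        inst2 = build_instance(sorted(shuffled, key=lambda p: p.read_id), seg, default_params)
        assert dict(inst1.matching_costs) == dict(inst2.matching_costs)
        assert inst1.X == inst2.X

    def test_linear_kind_tables(self):
        params = ScoringParams(coverage_cost_kind="linear")
        seg = segment_template(1000, 4, params)
        ps = [ReadPlacementSet(f"r{i}", (Placement(i, 0.0),)) for i in range(4)]
        inst = build_instance(ps, seg, params)
        assert inst.coverage_costs["seg000000"].costs == (4.0, 3.0, 2.0, 1.0, 0.0)


def _write_sam(path, records, template_id="tpl", length=5000):
    header = {"HD": {"VN": "1.6"}, "SQ": [{"SN": template_id, "LN": length}]}
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for rec in records:
            out.write(rec)


def _rec(header, name, flag, pos, mpos=-1, tag=("ZC", 0)):
    rec = pysam.AlignedSegment(header)
    rec.query_name = name
    rec.flag = flag
    if flag & 0x4:
        rec.reference_id = -1
        rec.reference_start = -1
    else:
        rec.reference_id = 0
        rec.reference_start = pos
        rec.cigarstring = "100M"
    rec.next_reference_id = 0 if mpos >= 0 else -1
    rec.next_reference_start = mpos
    rec.query_sequence = "A" * 100
    if tag is not None and not flag & 0x4:
        rec.set_tag(tag[0], tag[1], value_type="i")
    return rec


@pytest.fixture
def sam_header():
    return pysam.AlignmentHeader.from_dict(
        {"HD": {"VN": "1.6"}, "SQ": [{"SN": "tpl", "LN": 5000}]}
    )


class TestLoadPlacements:
    def test_concordant_pair_position_is_0_based_first_mate(
        self, tmp_path, sam_header, default_params
    ):
        # POS 101 (1-based) for the first mate -> placement position 100
        recs = [
            _rec(sam_header, "r0", 0x1 | 0x2 | 0x40 | 0x20, 100, mpos=300, tag=("ZC", 30)),
            _rec(sam_header, "r0", 0x1 | 0x2 | 0x80 | 0x10, 300, mpos=100, tag=("ZC", 40)),
        ]
        path = tmp_path / "a.sam"
        _write_sam(path, recs)
        assert "POS\t101" in path.read_text() or "\t101\t" in path.read_text()
        [ps] = load_placements(str(path), "tpl", default_params)
        assert ps.read_id == "r0"
        assert len(ps.placements) == 1
        assert ps.placements[0].position == 100
        assert ps.placements[0].cost == 70.0
        assert ps.placements[0].concordant

    def test_multiple_alignment_pairs(self, tmp_path, sam_header, default_params):
        recs = []
        for p1, p2 in ((100, 300), (1100, 1300), (2100, 2300)):
            recs.append(_rec(sam_header, "r0", 0x1 | 0x2 | 0x40 | 0x20, p1, mpos=p2))
            recs.append(_rec(sam_header, "r0", 0x1 | 0x2 | 0x80 | 0x10, p2, mpos=p1))
        path = tmp_path / "a.sam"
        _write_sam(path, recs)
        [ps] = load_placements(str(path), "tpl", default_params)
        assert len(ps.placements) == 3
        assert [p.position for p in ps.placements] == [100, 1100, 2100]

    def test_unmapped_pair_retained_empty(self, tmp_path, sam_header, default_params):
        recs = [_rec(sam_header, "r9", 0x1 | 0x4 | 0x8 | 0x40, -1, tag=None)]
        path = tmp_path / "a.sam"
        _write_sam(path, recs)
        [ps] = load_placements(str(path), "tpl", default_params)
        assert ps.placements == ()
        assert math.isinf(ps.best_cost)

    def test_discordant_end_gets_penalty(self, tmp_path, sam_header, default_params):
        recs = [_rec(sam_header, "r0", 0x1 | 0x40, 700, tag=("ZC", 30))]
        path = tmp_path / "a.sam"
        _write_sam(path, recs)
        [ps] = load_placements(str(path), "tpl", default_params)
        assert ps.placements[0].cost == 120.0
        assert not ps.placements[0].concordant

    def test_missing_template_rejected(self, tmp_path, sam_header, default_params):
        path = tmp_path / "a.sam"
        _write_sam(path, [])
        with pytest.raises(InstanceError, match="other"):
            load_placements(str(path), "other", default_params)

    def test_missing_cost_tag_names_read(self, tmp_path, sam_header, default_params):
        recs = [_rec(sam_header, "rbad", 0x1 | 0x40, 700, tag=None)]
        path = tmp_path / "a.sam"
        _write_sam(path, recs)
        with pytest.raises(InstanceError, match="rbad"):
            load_placements(str(path), "tpl", default_params)

    def test_record_order_invariance(self, tmp_path, sam_header, default_params):
        recs = [
            _rec(sam_header, "r1", 0x1 | 0x40, 700, tag=("ZC", 0)),
            _rec(sam_header, "r0", 0x1 | 0x2 | 0x40 | 0x20, 100, mpos=300),
            _rec(sam_header, "r0", 0x1 | 0x2 | 0x80 | 0x10, 300, mpos=100),
        ]
        p1 = tmp_path / "fwd.sam"
        p2 = tmp_path / "rev.sam"
        _write_sam(p1, recs)
        _write_sam(p2, recs[::-1])
        a = load_placements(str(p1), "tpl", default_params)
        b = load_placements(str(p2), "tpl", default_params)
        assert a == b
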