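"""Plate-table IO, background correction and viability normalization."""

import math

import pytest
from hypothesis import given, settings, strategies as st

from ctsynergy import (
    AbsorbanceRecord,
    SimAgentConfig,
    build_dose_response,
    correct_absorbance,
    read_plate_table,
    simulate_single_agent,
    write_plate_table,
)
from ctsynergy.errors import (
    DegenerateControlError,
    NormalizationError,
    PlateParseError,
    PlateSchemaError,
)


def make_record(**kw):
    defaults = dict(
        well_id="A1", condition="drug", dose1=1.0, dose2=0.0, time=72.0,
        a570=1.2, a650=0.2, replicate=1,
    )
    defaults.update(kw)
    return AbsorbanceRecord(**defaults)


def plate(condition="drug", doses=(0.0, 0.1, 1.0, 10.0), od_by_dose=None, replicates=(1, 2, 3), time=72.0):
    """Hand-built plate: corrected OD = od_by_dose[dose] for every replicate."""
    od_by_dose = od_by_dose or {0.0: 1.0, 0.1: 0.8, 1.0: 0.5, 10.0: 0.2}
    recs = []
    for d in doses:
        for rep in replicates:
            recs.append(make_record(well_id=f"w{d}r{rep}", condition=condition, dose1=d,
                                    a570=0.2 + od_by_dose[d], a650=0.2, replicate=rep, time=time))
    return recs


class TestAbsorbanceRecord:
    @pytest.mark.parametrize("bad", [dict(dose1=-1), dict(time=-1), dict(replicate=0),
                                     dict(a570=float("nan")), dict(a650=float("inf"))])
    def test_invariants_rejected(self, bad):
        with pytest.raises(ValueError):
            make_record(**bad)


class TestCorrectAbsorbance:
    def test_subtracts_reference(self):
        assert correct_absorbance(make_record(a570=1.20, a650=0.20)) == pytest.approx(1.00)

    def test_negative_od_returned_with_warning(self):
        with pytest.warns(UserWarning, match="negative corrected OD"):
            od = correct_absorbance(make_record(a570=0.15, a650=0.20))
        assert od == pytest.approx(-0.05)

    def test_noise_free_generator_inverse(self):
        """Zero-noise simulated wells correct to exactly od_bg + od_max * fu."""
        cfg = SimAgentConfig(name="d", dm=2.0, m=0.8, od_bg=0.1, od_max=0.9, noise_sd=0.0, seed=5)
        for rec in simulate_single_agent(cfg):
            if rec.time == 0:
                fu = 1.0
            elif rec.dose1 == 0:
                fu = 1.0
            else:
                dm_t = cfg.dm * (1 + cfg.potency_half_time / rec.time)
                fu = 1.0 / (1.0 + (rec.dose1 / dm_t) ** cfg.m)
            assert rec.a570 - rec.a650 == pytest.approx(cfg.od_bg + cfg.od_max * fu, abs=1e-12)


class TestPlateTableIO:
    def test_round_trip_identity(self, tmp_path):
        records = simulate_single_agent(SimAgentConfig(name="x", dm=3.0, m=1.1, seed=42))
        path = tmp_path / "plate.csv"
        write_plate_table(records, path)
        assert read_plate_table(path) == records

    def test_three_row_file(self, tmp_path):
        path = tmp_path / "p.csv"
        path.write_text(
            "well,condition,dose1_uM,dose2_uM,time_h,a570,a650,replicate\n"
            "A1,control,0,0,72,1.0,0.05,1\n"
            "A2,drug,1,0,72,0.6,0.05,1\n"
            "A3,drug,10,0,72,0.3,0.05,1\n"
        )
        recs = read_plate_table(path)
        assert [r.dose1 for r in recs] == [0.0, 1.0, 10.0]

    def test_missing_column_names_it(self, tmp_path):
        path = tmp_path / "p.csv"
        path.write_text("well,condition,dose1_uM,dose2_uM,time_h,a570,replicate\nA1,c,0,0,72,1.0,1\n")
        with pytest.raises(PlateSchemaError) as err:
            read_plate_table(path)
        assert err.value.missing == ["a650"]

    def test_non_numeric_row_reported_with_number(self, tmp_path):
        path = tmp_path / "p.csv"
        path.write_text(
            "well,condition,dose1_uM,dose2_uM,time_h,a570,a650,replicate\n"
            "A1,c,0,0,72,1.0,0.05,1\n"
            "A2,c,1,0,72,oops,0.05,1\n"
        )
        with pytest.raises(PlateParseError) as err:
            read_plate_table(path)
        assert err.value.bad_rows[0][0] == 3

    def test_column_remap_and_tab_dialect(self, tmp_path):
        path = tmp_path / "p.tsv"
        path.write_text(
            "Well\tcondition\tdose1_uM\tdose2_uM\ttime_h\tOD570\ta650\treplicate\n"
            "A1\tc\t0\t0\t72\t1.0\t0.05\t1\n"
        )
        recs = read_plate_table(path, delimiter="\t", column_map={"a570": "OD570"})
        assert recs[0].a570 == pytest.approx(1.0)


class TestBuildDoseResponse:
    def test_fraction_affected_definition(self):
        """Control OD 1.0, treated 0.25 -> fu 0.25, fa 0.75."""
        recs = plate(od_by_dose={0.0: 1.0, 0.1: 0.9, 1.0: 0.25, 10.0: 0.1})
        table = build_dose_response(recs, "drug", 72.0)
        by_dose = {p.dose1: p for p in table.points}
        assert by_dose[1.0].fa_mean == pytest.approx(0.75)

    def test_treated_above_control_clips_to_eps(self):
        recs = plate(od_by_dose={0.0: 1.0, 0.1: 1.10, 1.0: 0.5, 10.0: 0.2})
        table = build_dose_response(recs, "drug", 72.0)
        by_dose = {p.dose1: p for p in table.points}
        assert by_dose[0.1].fa_mean == pytest.approx(0.005)

    def test_negative_od_floors_at_full_kill(self):
        recs = plate(od_by_dose={0.0: 1.0, 0.1: 0.9, 1.0: 0.5, 10.0: -0.05})
        table = build_dose_response(recs, "drug", 72.0)
        by_dose = {p.dose1: p for p in table.points}
        assert by_dose[10.0].fa_mean == pytest.approx(0.995)
        assert len(table.negative_od_wells) == 3

    def test_zero_dose_row_excluded_from_fit(self):
        table = build_dose_response(plate(), "drug", 72.0)
        assert table.points[0].dose1 == 0.0 and table.points[0].excluded_from_fit
        doses, _ = table.fit_points()
        assert 0.0 not in doses

    def test_no_controls_raises(self):
        recs = [r for r in plate() if r.dose1 > 0]
        with pytest.raises(NormalizationError):
            build_dose_response(recs, "drug", 72.0)

    def test_degenerate_control_raises(self):
        recs = plate(od_by_dose={0.0: -0.2, 0.1: 0.9, 1.0: 0.5, 10.0: 0.2})
        with pytest.raises(DegenerateControlError):
            build_dose_response(recs, "drug", 72.0)

    def test_noise_free_round_trip_recovers_fa(self):
        """With sd 0 and no background the recovered fa equals 1 - fu exactly."""
        cfg = SimAgentConfig(name="d", dm=1.0, m=1.0, noise_sd=0.0, seed=7)
        table = build_dose_response(simulate_single_agent(cfg), "d", 72.0)
        dm72 = cfg.dm * (1 + cfg.potency_half_time / 72.0)
        for p in table.points:
            if p.excluded_from_fit:
                continue
            fa_true = 1.0 - 1.0 / (1.0 + (p.dose1 / dm72) ** cfg.m)
            assert p.fa_mean == pytest.approx(max(0.005, min(0.995, fa_true)), abs=1e-12)

    @given(scale=st.floats(0.1, 10.0))
    @settings(max_examples=25, deadline=None)
    def test_normalization_scale_invariance(self, scale):
        """Multiplying every corrected OD by a constant leaves all fa unchanged."""
        od = {0.0: 1.0, 0.1: 0.8, 1.0: 0.5, 10.0: 0.2}
        base = build_dose_response(plate(od_by_dose=od), "drug", 72.0)
        scaled_od = {d: v * scale for d, v in od.items()}
        scaled = build_dose_response(plate(od_by_dose=scaled_od), "drug", 72.0)
        for p, q in zip(base.points, scaled.points):
            assert p.fa_replicates == pytest.approx(q.fa_replicates)

    def test_replicate_count_preserved(self):
        table = build_dose_response(plate(), "drug", 72.0)
        for p in table.points[1:]:
            assert len(p.fa_replicates) == 3

    def test_all_fa_within_clip_bounds(self):
        recs = simulate_single_agent(SimAgentConfig(name="d", dm=0.05, m=2.0, noise_sd=0.05, seed=3))
        table = build_dose_response(recs, "d", 72.0)
        for p in table.points:
            for fa in p.fa_replicates:
                assert 0.005 <= fa <= 0.995

    def test_per_replicate_pairing_mode(self):
        recs = []
        ods = {1: 1.0, 2: 2.0}  # control OD differs by replicate
        for rep, ctrl in ods.items():
            recs.append(make_record(well_id=f"c{rep}", dose1=0.0, a570=0.2 + ctrl, replicate=rep))
            recs.append(make_record(well_id=f"t{rep}", dose1=1.0, a570=0.2 + ctrl / 2, replicate=rep))
            recs.append(make_record(well_id=f"u{rep}", dose1=10.0, a570=0.2 + ctrl / 4, replicate=rep))
        table = build_dose_response(recs, "drug", 72.0, control_pairing="per-replicate")
        by_dose = {p.dose1: p for p in table.points}
        assert by_dose[1.0].fa_replicates == pytest.approx((0.5, 0.5))
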