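"""Point-table construction, total scores, risk groups, SPS, stratification."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from palliscore import (
    Cohort,
    PatientRecord,
    apply_table,
    assign_points,
    assign_risk_group,
    derive_point_table,
    evaluate_stratification,
    planted_rate_cohort,
    read_point_table,
    reference_point_table,
    sps_assign,
    sps_from_record,
    total_score,
    write_point_table,
)
from palliscore.score import DEVELOPMENT_COHORT_RATES, SCORE_FACTORS, PointTable


class TestAssignPoints:
    @pytest.mark.parametrize(
        "rate,expected",
        [(2, 0.0), (15, 1.5), (4, 0.0), (11, 1.0), (33, 3.0), (3, 0.0), (0, 0.0)],
    )
    def test_v1_floor_to_half(self, rate, expected):
        assert assign_points(rate, "v1") == expected

    @pytest.mark.parametrize(
        "rate,expected",
        [(7, 1), (39, 4), (8, 1), (49, 5), (14, 1), (50, 5), (10, 1), (28, 3), (0, 0)],
    )
    def test_v2_round_half_up(self, rate, expected):
        assert assign_points(rate, "v2") == expected

    def test_out_of_range_rate_rejected(self):
        with pytest.raises(ValueError):
            assign_points(101.0, "v1")
        with pytest.raises(ValueError):
            assign_points(-1.0, "v2")

    def test_unknown_variant_rejected(self):
        with pytest.raises(ValueError, match="variant"):
            assign_points(10.0, "v3")

    @settings(max_examples=200, derandomize=True)
    @given(
        a=st.floats(min_value=0, max_value=100),
        b=st.floats(min_value=0, max_value=100),
        variant=st.sampled_from(["v1", "v2"]),
    )
    def test_monotone_in_rate(self, a, b, variant):
        lo, hi = sorted((a, b))
        assert assign_points(lo, variant) <= assign_points(hi, variant)


def _full_patient(adverse: bool) -> PatientRecord:
    kps = 50 if adverse else 90
    return PatientRecord(
        "x", 1.0, True, kps=kps, steroids=adverse, liver_mets=adverse,
        pleural_effusion=adverse, primary_site="prostate", bone_mets_only=True,
    )


class TestTotalScore:
    @pytest.mark.parametrize(
        "variant,adverse,expected",
        [("v2", True, 17.0), ("v2", False, 4.0), ("v1", True, 6.5), ("v1", False, 0.0)],
    )
    def test_published_extremes(self, variant, adverse, expected):
        table = reference_point_table(variant)
        res = total_score(_full_patient(adverse), table)
        assert res.total == expected
        assert res.assignable

    def test_table_bounds_match_extremes(self):
        t1, t2 = reference_point_table("v1"), reference_point_table("v2")
        assert (t1.min_total, t1.max_total) == (0.0, 6.5)
        assert (t2.min_total, t2.max_total) == (4.0, 17.0)

    def test_missing_component_unassignable(self):
        p = _full_patient(True)
        p.steroids = None
        res = total_score(p, reference_point_table("v2"))
        assert not res.assignable
        assert res.total is None
        assert res.components["steroids"] is None

    def test_monotone_in_each_factor(self):
        """Switching any single factor favorable -> adverse never decreases
        the total, for both variants."""
        for variant in ("v1", "v2"):
            table = reference_point_table(variant)
            base = total_score(_full_patient(False), table).total
            for fname in SCORE_FACTORS:
                p = _full_patient(False)
                if fname == "kps_le60":
                    p.kps = 50
                else:
                    setattr(p, fname, True)
                assert total_score(p, table).total >= base

    def test_total_is_sum_of_components(self):
        table = reference_point_table("v2")
        p = _full_patient(True)
        p.liver_mets = False
        res = total_score(p, table)
        assert res.total == pytest.approx(sum(res.components.values()))


class TestRiskGroups:
    @pytest.mark.parametrize(
        "variant,total,group",
        [
            ("v1", 0.0, 1),
            ("v1", 0.5, 2),
            ("v1", 1.5, 2),
            ("v1", 2.0, 3),
            ("v1", 3.0, 3),
            ("v1", 3.5, 4),
            ("v1", 6.5, 4),
            ("v2", 4, 1),
            ("v2", 5, 1),
            ("v2", 6, 2),
            ("v2", 7, 2),
            ("v2", 8, 2),
            ("v2", 9, 3),
            ("v2", 11, 3),
            ("v2", 12, 4),
            ("v2", 17, 4),
        ],
    )
    def test_default_cutpoints(self, variant, total, group):
        assert assign_risk_group(total, variant) == group

    def test_out_of_bounds_total_rejected(self):
        with pytest.raises(ValueError, match="attainable"):
            assign_risk_group(7.0, "v1")
        with pytest.raises(ValueError, match="attainable"):
            assign_risk_group(3.0, "v2")

    def test_custom_cutpoints(self):
        assert assign_risk_group(2.0, "v1", cutpoints=(2.0, 4.0, 6.0)) == 1

    def test_group_monotone_in_total(self):
        totals = [4, 5, 6, 7, 8, 9, 10, 11, 12, 13, 17]
        groups = [assign_risk_group(t, "v2") for t in totals]
        assert groups == sorted(groups)


class TestDerivePointTable:
    def test_planted_rates_recover_published_v1_cells(self):
        cohort = planted_rate_cohort(
            {"<=60": 0.15, "70-100": 0.02}, 20_000, seed=31, horizon=1.0
        )
        table = derive_point_table(cohort, ["kps_le60"], 1.0, "v1")
        assert table.points_for("kps_le60", "<=60") == 1.5
        assert table.points_for("kps_le60", "70-100") == 0.0

    def test_planted_rates_recover_published_v2_cells(self):
        cohort = planted_rate_cohort(
            {"yes": 0.49, "no": 0.08}, 20_000, seed=32, horizon=2.0, factor="liver_mets"
        )
        table = derive_point_table(cohort, ["liver_mets"], 2.0, "v2")
        assert table.points_for("liver_mets", "yes") == 5.0
        assert table.points_for("liver_mets", "no") == 1.0

    def test_no_deaths_before_horizon_all_zero(self):
        cohort = planted_rate_cohort(
            {"yes": 0.0, "no": 0.0}, 200, seed=33, horizon=2.0, factor="steroids"
        )
        table = derive_point_table(cohort, ["steroids"], 2.0, "v2")
        assert table.points_for("steroids", "yes") == 0.0
        assert table.points_for("steroids", "no") == 0.0

    def test_empty_level_names_factor_and_level(self):
        cohort = planted_rate_cohort({"yes": 0.2}, 50, seed=34, horizon=1.0, factor="steroids")
        with pytest.raises(ValueError, match=r"'no'.*'steroids'|'steroids'.*'no'"):
            derive_point_table(cohort, ["steroids"], 1.0, "v1")

    def test_round_trip_csv(self, tmp_path):
        table = reference_point_table("v2")
        path = write_point_table(table, tmp_path / "t.csv")
        back = read_point_table(path)
        assert back.variant == "v2"
        assert back.entries == table.entries
        assert back.factors == table.factors

    def test_rounding_resolution_invariants_enforced(self):
        from palliscore.score import PointEntry

        with pytest.raises(ValueError, match="integer"):
            PointTable("v2", 2.0, {("steroids", "yes"): PointEntry(15.0, 1.5)}, ("steroids",))
        with pytest.raises(ValueError, match="0.5"):
            PointTable("v1", 1.0, {("steroids", "yes"): PointEntry(15.0, 1.2)}, ("steroids",))


class TestSPS:
    @pytest.mark.parametrize(
        "flags,group,count",
        [
            ((True, True, True), "poor", 3),
            ((True, True, False), "intermediate", 2),
            ((True, False, True), "intermediate", 2),
            ((False, True, True), "intermediate", 2),
            ((True, False, False), "good", 1),
            ((False, False, False), "good", 0),
        ],
    )
    def test_rule(self, flags, group, count):
        res = sps_assign(*flags)
        assert res.group == group
        assert res.adverse_count == count

    def test_missing_input_unassignable(self):
        assert sps_assign(None, True, True).group == "unassignable"
        assert sps_assign(True, True, None).adverse_count is None

    def test_from_record(self):
        p = PatientRecord(
            "x", 1.0, True, kps=50, primary_site="nsclc", bone_mets_only=False
        )
        assert sps_from_record(p).group == "poor"
        p2 = PatientRecord(
            "y", 1.0, True, kps=90, primary_site="breast", bone_mets_only=True
        )
        assert sps_from_record(p2).group == "good"
        p3 = PatientRecord("z", 1.0, True, kps=50, primary_site="nsclc")
        assert sps_from_record(p3).group == "unassignable"


class TestEvaluateStratification:
    def _cohort_groups(self, medians, n_per_group, rng):
        recs, groups = [], {}
        i = 0
        for g, m in enumerate(medians, start=1):
            times = rng.exponential(m / np.log(2), n_per_group)
            for t in times:
                recs.append(PatientRecord(f"p{i}", float(t), True))
                groups[f"p{i}"] = str(g)
                i += 1
        return Cohort(recs), groups

    def test_copy_groups_identical_medians_p_one(self, rng):
        times = rng.exponential(5, 30)
        recs = [PatientRecord(f"a{i}", float(t), True) for i, t in enumerate(times)]
        recs += [PatientRecord(f"b{i}", float(t), True) for i, t in enumerate(times)]
        groups = {r.id: r.id[0] for r in recs}
        report = evaluate_stratification(Cohort(recs), groups)
        meds = [g.median_months for g in report.groups]
        assert meds[0] == meds[1]
        assert all(p == pytest.approx(1.0) for p in report.pairwise_p.values())

    def test_all_dead_before_two_months_rate_100(self, rng):
        recs = [
            PatientRecord(f"a{i}", float(t), True)
            for i, t in enumerate(rng.uniform(0.1, 1.5, 20))
        ]
        recs += [
            PatientRecord(f"b{i}", float(t), True)
            for i, t in enumerate(rng.exponential(10, 20))
        ]
        groups = {r.id: r.id[0] for r in recs}
        report = evaluate_stratification(Cohort(recs), groups)
        g_a = next(g for g in report.groups if g.label == "a")
        assert g_a.death_rate_2mo == pytest.approx(100.0)

    def test_single_group_rejected(self, rng):
        recs = [PatientRecord(f"p{i}", 1.0 + i, True) for i in range(5)]
        with pytest.raises(ValueError, match="two non-empty groups"):
            evaluate_stratification(Cohort(recs), {r.id: "1" for r in recs})

    def test_planted_tier_medians_recovered_in_order(self, rng):
        """Groups planted at medians 24/10/3/1 months, n=100/group: the
        recovered medians are strictly decreasing in >= 95% of replicates."""
        reps, hits = 200, 0
        for _ in range(reps):
            cohort, groups = self._cohort_groups((24.0, 10.0, 3.0, 1.0), 100, rng)
            report = evaluate_stratification(cohort, groups)
            meds = [g.median_months for g in sorted(report.groups, key=lambda g: g.label)]
            if all(m is not None for m in meds) and all(
                a > b for a, b in zip(meds, meds[1:])
            ):
                hits += 1
        assert hits / reps >= 0.95

    def test_apply_then_evaluate_end_to_end(self, rng):
        cohort = planted_rate_cohort(
            {"<=60": [(1.0, 0.15), (2.0, 0.39)], "70-100": [(1.0, 0.02), (2.0, 0.07)]},
            500,
            seed=35,
        )
        table = reference_point_table("v2")
        results = apply_table(cohort, table)
        assert all(r.assignable for r in results)
        report = evaluate_stratification(cohort, results)
        assert len(report.groups) == 2
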