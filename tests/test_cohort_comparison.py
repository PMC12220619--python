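"""Tolerance-gated f comparisons, the 8-of-11 count and the A-D trend groups."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from swirf.cohort_comparison import (
    Direction,
    TrendGroup,
    build_profiles,
    classify_all,
    classify_trend_group,
    count_increased,
    difference_record,
    difference_table,
    profile_table,
    relative_difference,
)
from swirf.outlier_stats import PUBLISHED_TOLERANCE
from swirf.synthetic_data import SimulationConfig, simulate_treatment_study

from conftest import make_scan


class TestDifferenceRecord:
    def test_clear_increase_calls_younger(self):
        rec = difference_record(0.0641, 0.0240, 0.0008)
        assert rec.actual == pytest.approx(0.0401)
        assert not rec.gated
        assert rec.direction is Direction.YOUNGER
        assert rec.relative == pytest.approx(2.670833, abs=1e-6)

    def test_within_tolerance_is_gated_no_change(self):
        rec = difference_record(0.0022, 0.0018, 0.0008)
        assert rec.actual == pytest.approx(0.0004)
        assert rec.gated
        assert rec.direction is Direction.NO_CHANGE
        assert rec.relative == 0.0

    def test_equal_values_always_gated(self):
        rec = difference_record(0.05, 0.05, 0.0)
        assert rec.actual == 0.0 and rec.gated

    def test_relative_difference_examples(self):
        assert relative_difference(0.0641, 0.0240) == pytest.approx(2.7, abs=0.05)
        assert relative_difference(0.0261, 0.0022) == pytest.approx(11.9, abs=0.05)
        assert relative_difference(0.0022, 0.0018) == 0.0  # gated

    def test_zero_earlier_ungated_flagged_undefined(self):
        rec = difference_record(0.05, 0.0, 0.0008)
        assert rec.undefined and np.isnan(rec.relative)


@settings(max_examples=50, deadline=None, derandomize=True)
@given(
    f1=st.floats(0, 1, allow_nan=False),
    f2=st.floats(0, 1, allow_nan=False),
    tau=st.floats(0, 0.1, allow_nan=False),
)
def test_direction_antisymmetric(f1, f2, tau):
    """Swapping later/earlier flips younger<->older and preserves no_change."""
    fwd = difference_record(f1, f2, tau)
    rev = difference_record(f2, f1, tau)
    assert fwd.actual == -rev.actual
    flip = {
        Direction.YOUNGER: Direction.OLDER,
        Direction.OLDER: Direction.YOUNGER,
        Direction.NO_CHANGE: Direction.NO_CHANGE,
    }
    assert rev.direction is flip[fwd.direction]


@settings(max_examples=50, deadline=None, derandomize=True)
@given(
    f1=st.floats(0, 1, allow_nan=False),
    f2=st.floats(0, 1, allow_nan=False),
    tau_small=st.floats(0, 0.05, allow_nan=False),
    extra=st.floats(0, 0.05, allow_nan=False),
)
def test_gating_monotone_in_tolerance(f1, f2, tau_small, extra):
    """A larger tolerance never un-gates a gated pair."""
    small = difference_record(f1, f2, tau_small)
    large = difference_record(f1, f2, tau_small + extra)
    if small.gated:
        assert large.gated


class TestCountIncreased:
    def test_published_study_has_eight_of_eleven(self, fixture_f):
        assert count_increased(fixture_f) == 8

    def test_no_change_counts_zero(self, fixture_f):
        flat = fixture_f.copy()
        flat["f_post_combined"] = flat["f_pre"]
        assert count_increased(flat) == 0


class TestTrendClassifier:
    @pytest.mark.parametrize(
        "species,abundance,f,expected",
        [
            ("Ae. vexans", (74, 63, 88), (0.0163, 0.0438, 0.0267), TrendGroup.A),
            ("An. quadrimaculatus", (23, 16, 16), (0.0513, 0.0127, 0.0626), TrendGroup.C),
            ("Ps. ferox", (239, 70, 126), (0.0951, 0.0942, 0.0624), TrendGroup.D),
        ],
    )
    def test_named_examples(self, species, abundance, f, expected):
        cls = classify_trend_group(abundance, f, PUBLISHED_TOLERANCE, species=species)
        assert cls.group is expected

    def test_full_study_grouping(self, fixture_metadata, fixture_f):
        groups = classify_all(fixture_metadata, fixture_f, PUBLISHED_TOLERANCE)
        by_group = {
            g: set(groups.index[groups["group"] == g]) for g in "ABCD"
        }
        assert by_group["A"] == {"Ae. vexans", "Cq. perturbans", "Cs. melanura"}
        assert by_group["B"] == {"Ae. cinereus", "Oc. abserratus", "Oc. canadensis"}
        assert by_group["C"] == {"Oc. excrucians", "An. quadrimaculatus"}
        assert by_group["D"] == {
            "Cx. pipiens/restuans", "An. punctipennis", "Ps. ferox",
        }

    def test_matches_published_column(self, fixture_metadata, fixture_f):
        groups = classify_all(fixture_metadata, fixture_f, PUBLISHED_TOLERANCE)
        assert (
            groups["group"] == fixture_metadata.loc[groups.index, "published_group"]
        ).all()

    def test_predicates_exported(self):
        cls = classify_trend_group((100, 50, 120), (0.01, 0.05, 0.02), 0.0008)
        assert cls.predicates["abundance_down_d1"]
        assert cls.predicates["abundance_recovered_d2"]
        assert cls.group is TrendGroup.A


class TestDifferenceTable:
    def test_published_cells(self, fixture_f):
        t = difference_table(fixture_f, PUBLISHED_TOLERANCE)
        assert t.loc["Ae. cinereus", "actual_d1_pre"] == 0.0401
        assert t.loc["Cx. pipiens/restuans", "actual_d1_pre"] == 0.0581
        assert t.loc["Oc. excrucians", "actual_d1_pre"] == 0.0004
        assert bool(t.loc["Oc. excrucians", "gated_d1_pre"])
        assert t.loc["Ae. cinereus", "relative_d1_pre"] == 2.7
        assert t.loc["Cs. melanura", "relative_d1_pre"] == 3.5
        assert t.loc["An. quadrimaculatus", "relative_d2_d1"] == 4.9
        assert t.loc["Oc. excrucians", "relative_d2_d1"] == 11.9
        assert t.loc["Oc. excrucians", "relative_d1_pre"] == 0.0

    def test_only_one_gated_cell_in_study(self, fixture_f):
        t = difference_table(fixture_f, PUBLISHED_TOLERANCE)
        assert int(t["gated_d1_pre"].sum()) == 1
        assert int(t["gated_d2_d1"].sum()) == 0


class TestBuildProfiles:
    def test_synthetic_study_profiles_complete(self):
        cfg = SimulationConfig(
            seed=11, n_specimens=10, n_cycles=1,
            species=("Sim sp. 1", "Sim sp. 2", "Sim sp. 3"),
        )
        profiles = build_profiles(simulate_treatment_study(cfg).scans)
        assert len(profiles) == 3
        assert all(p.complete for p in profiles)
        table = profile_table(profiles)
        assert set(table.index) == set(cfg.species)
        assert (table[["f_pre", "f_post_d1", "f_post_d2"]] >= 0).all().all()

    def test_missing_day_class_flagged(self):
        scans = []
        rng = np.random.default_rng(0)
        for i in range(6):
            scans.append(
                make_scan(rng.normal(size=5), specimen_id=f"p{i}", day="PRE")
            )
            scans.append(
                make_scan(rng.normal(size=5), specimen_id=f"q{i}", day="POST_D1")
            )
        with pytest.warns(UserWarning, match="d2 cohort"):
            profiles = build_profiles(scans)
        p = profiles[0]
        assert p.f_d2 is None
        assert p.f_pre is not None and p.f_post_combined is not None

    def test_combined_is_recomputed_not_averaged(self):
        rng = np.random.default_rng(3)
        scans = []
        for i in range(12):
            scans.append(
                make_scan(rng.normal(0, 1, 6), specimen_id=f"a{i}", day="POST_D1")
            )
            # d2 cohort has a different spectral shape (per-wavelength shift
            # survives SNV, unlike a constant offset), so pooling moves the
            # fences
            scans.append(
                make_scan(
                    rng.normal(0, 1, 6) + np.array([4.0, 0, 0, 0, 0, -4.0]),
                    specimen_id=f"b{i}", day="POST_D2",
                )
            )
            scans.append(
                make_scan(rng.normal(0, 1, 6), specimen_id=f"c{i}", day="PRE")
            )
        p = build_profiles(scans)[0]
        weighted = 0.5 * p.f_d1 + 0.5 * p.f_d2
        assert p.f_post_combined != pytest.approx(weighted, abs=1e-12)
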