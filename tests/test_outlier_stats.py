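"""Tukey fences, outlier counting vs a brute-force oracle, f, and tolerance."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from swirf.outlier_stats import (
    FenceSet,
    cohort_outlier_fraction,
    cohort_outlier_fraction_matrix,
    compute_fences,
    count_outlier_points,
    measurement_tolerance,
)

from conftest import make_scan


def oracle_count(values: np.ndarray, k: float = 1.5, eps: float = 1e-12) -> int:
    """Independent double-loop count with per-column quartiles (same
    on-the-fence numerical guard as the implementation)."""
    n, p = values.shape
    count = 0
    for j in range(p):
        col = values[:, j]
        q1 = np.quantile(col, 0.25)
        q3 = np.quantile(col, 0.75)
        lo, hi = q1 - k * (q3 - q1), q3 + k * (q3 - q1)
        tol_lo = eps * max(1.0, abs(lo))
        tol_hi = eps * max(1.0, abs(hi))
        for i in range(n):
            if values[i, j] < lo - tol_lo or values[i, j] > hi + tol_hi:
                count += 1
    return count


class TestComputeFences:
    def test_hand_computed_quartiles(self):
        fs = compute_fences(np.array([[1.0], [2.0], [3.0], [4.0], [5.0]]), k=1.5)
        assert fs.q1[0] == 2.0 and fs.q3[0] == 4.0
        assert fs.lower[0] == -1.0 and fs.upper[0] == 7.0

    def test_constant_column_collapses(self):
        fs = compute_fences(np.full((5, 2), 3.0))
        np.testing.assert_array_equal(fs.lower, [3.0, 3.0])
        np.testing.assert_array_equal(fs.upper, [3.0, 3.0])

    def test_k_zero_fences_are_quartiles(self):
        fs = compute_fences(np.arange(8.0).reshape(8, 1), k=0.0)
        assert fs.lower[0] == fs.q1[0]
        assert fs.upper[0] == fs.q3[0]

    def test_too_few_scans_rejected(self):
        with pytest.raises(ValueError, match="at least 4"):
            compute_fences(np.ones((3, 2)))

    def test_tukey_hinges_alternative(self):
        # n=5: hinges are medians of {1,2,3} and {3,4,5}
        fs = compute_fences(
            np.array([[1.0], [2.0], [3.0], [4.0], [5.0]]), method="tukey"
        )
        assert fs.q1[0] == 2.0 and fs.q3[0] == 4.0


class TestCountOutliers:
    def test_planted_single_outlier(self):
        base = np.tile([1.0, 2.0, 3.0], (4, 1))
        spiked = np.vstack([base, [1.0, 12.0, 3.0]])
        fences = compute_fences(spiked)
        assert count_outlier_points(spiked, fences) == 1

    def test_identical_rows_no_outliers(self):
        m = np.tile([1.0, 5.0], (6, 1))
        assert count_outlier_points(m, compute_fences(m)) == 0

    def test_boundary_point_not_an_outlier(self):
        fences = FenceSet(q1=np.array([2.0]), q3=np.array([4.0]), k=1.5)
        # upper fence is exactly 7.0
        assert count_outlier_points(np.array([[7.0]] * 5), fences) == 0
        assert count_outlier_points(np.array([[7.0 + 1e-9]] * 5), fences) == 5

    def test_dimension_mismatch(self):
        fences = compute_fences(np.ones((5, 3)) + np.arange(5)[:, None])
        with pytest.raises(ValueError, match="columns"):
            count_outlier_points(np.ones((5, 2)), fences)


@settings(max_examples=60, deadline=None, derandomize=True)
@given(
    values=arrays(
        np.float64,
        st.tuples(st.integers(4, 10), st.integers(1, 10)),
        elements=st.floats(-50, 50, allow_nan=False, width=32),
    ),
    k=st.sampled_from([0.0, 1.0, 1.5, 3.0]),
)
def test_count_matches_bruteforce_oracle(values, k):
    """Vectorised fencing+counting agrees exactly with the double loop."""
    fences = compute_fences(values, k=k)
    assert count_outlier_points(values, fences) == oracle_count(values, k)


@settings(max_examples=30, deadline=None, derandomize=True)
@given(
    values=arrays(
        np.float64,
        st.tuples(st.integers(4, 8), st.integers(1, 6)),
        elements=st.floats(-50, 50, allow_nan=False, width=32),
    ),
)
def test_outlier_count_weakly_decreasing_in_k(values):
    counts = [
        count_outlier_points(values, compute_fences(values, k=k))
        for k in (0.0, 0.5, 1.0, 1.5, 2.0, 3.0)
    ]
    assert counts == sorted(counts, reverse=True)


class TestCohortOutlierFraction:
    def test_planted_outlier_gives_one_fifteenth(self):
        # 5 scans x 3 points: four scans with modest spread plus a copy of
        # the first with +10 on the last wavelength; the brute-force oracle
        # on the SNV matrix confirms exactly one cell beyond the fences
        base = np.array(
            [
                [0.86194186, 2.22295918, 2.97525649],
                [1.02431631, 1.91278500, 3.34637092],
                [0.99355823, 1.33987530, 2.79237823],
                [0.40936102, 1.02456848, 2.84096540],
            ]
        )
        spiked = base[0].copy()
        spiked[2] += 10.0
        scans = [make_scan(b, specimen_id=f"m{i}") for i, b in enumerate(base)]
        scans.append(make_scan(spiked, specimen_id="m4"))
        from swirf.preprocessing import snv_transform_matrix

        assert oracle_count(snv_transform_matrix(scans).values) == 1
        res = cohort_outlier_fraction(scans)
        assert res.total_points == 15
        assert res.outlier_points == 1
        assert res.f == pytest.approx(1 / 15)

    def test_affine_scatter_invariance_of_f(self, rng):
        spectra = rng.normal(size=(6, 10))
        scans_a = [make_scan(s, specimen_id=f"m{i}") for i, s in enumerate(spectra)]
        scans_b = [
            make_scan(rng.uniform(0.2, 3.0) * s + rng.uniform(-5, 5),
                      specimen_id=f"m{i}")
            for i, s in enumerate(spectra)
        ]
        assert cohort_outlier_fraction(scans_a).f == pytest.approx(
            cohort_outlier_fraction(scans_b).f
        )

    def test_f_zero_for_identical_scans_up_to_scatter(self, rng):
        shape = rng.normal(size=6)
        scans = [
            make_scan(rng.uniform(0.5, 2) * shape + rng.uniform(-1, 1),
                      specimen_id=f"m{i}")
            for i in range(5)
        ]
        assert cohort_outlier_fraction(scans).f == 0.0

    def test_f_invariant_to_wavelength_order(self, rng):
        values = rng.normal(size=(8, 6))
        perm = rng.permutation(6)
        f1 = cohort_outlier_fraction_matrix(values).f
        f2 = cohort_outlier_fraction_matrix(values[:, perm]).f
        assert f1 == f2

    def test_pooled_f_is_not_weighted_mean_of_subcohorts(self, rng):
        # two sub-cohorts with different centres: pooling shifts the fences
        a = rng.normal(0.0, 1.0, size=(10, 5))
        b = rng.normal(4.0, 1.0, size=(10, 5))
        f_a = cohort_outlier_fraction_matrix(a).f
        f_b = cohort_outlier_fraction_matrix(b).f
        f_pool = cohort_outlier_fraction_matrix(np.vstack([a, b])).f
        weighted = 0.5 * f_a + 0.5 * f_b
        assert f_pool != pytest.approx(weighted, abs=1e-12)


class TestMeasurementTolerance:
    @pytest.mark.parametrize(
        "trials,expected",
        [
            ([0.0105, 0.0113], 0.0008),
            ([0.25, 0.25], 0.0),
            ([0.01, 0.012, 0.011], 0.002),
        ],
    )
    def test_max_pairwise_difference(self, trials, expected):
        assert measurement_tolerance(trials).value == pytest.approx(expected)

    def test_needs_two_trials(self):
        with pytest.raises(ValueError, match="at least 2"):
            measurement_tolerance([0.01])
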