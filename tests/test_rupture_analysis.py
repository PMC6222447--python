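"""Force-curve parsing and rupture statistics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from rdmpull.rupture_analysis import (
    ForceCurve,
    RuptureStats,
    aggregate_ruptures,
    compare_directions,
    peak_force,
    read_force_xvg,
    write_force_xvg,
)


def test_xvg_parse_skips_headers(tmp_path):
    p = tmp_path / "f.xvg"
    p.write_text(
        "# comment\n@    title \"x\"\n@ yaxis label \"F\"\n"
        "0.0 1.0\n1.0 2.0\n2.0 5.0\n3.0 4.0\n4.0 1.0\n"
    )
    curve = read_force_xvg(p)
    assert len(curve) == 5
    assert curve.extension is None
    assert curve.force[2] == 5.0


def test_xvg_three_column_and_round_trip(tmp_path):
    curve = ForceCurve(
        time=np.arange(5.0),
        extension=np.linspace(0, 0.4, 5),
        force=np.array([0.0, 10.0, 30.0, 20.0, 5.0]),
    )
    path = write_force_xvg(curve, tmp_path / "rt.xvg")
    back = read_force_xvg(path)
    np.testing.assert_allclose(back.time, curve.time)
    np.testing.assert_allclose(back.extension, curve.extension)
    np.testing.assert_allclose(back.force, curve.force)


def test_xvg_malformed_row_names_line(tmp_path):
    p = tmp_path / "bad.xvg"
    p.write_text("0.0 1.0\n1.0 oops\n")
    with pytest.raises(ValueError, match=":2"):
        read_force_xvg(p)
    p2 = tmp_path / "ragged.xvg"
    p2.write_text("0.0 1.0\n1.0 2.0 3.0\n")
    with pytest.raises(ValueError, match="ragged"):
        read_force_xvg(p2)
    p3 = tmp_path / "empty.xvg"
    p3.write_text("# nothing\n")
    with pytest.raises(ValueError, match="no numeric rows"):
        read_force_xvg(p3)


def test_force_curve_validation():
    with pytest.raises(ValueError, match="strictly increasing"):
        ForceCurve(time=[0.0, 0.0, 1.0], force=[1, 2, 3])
    with pytest.raises(ValueError, match="lengths differ"):
        ForceCurve(time=[0.0, 1.0], force=[1, 2, 3])


def test_peak_force_triangle_and_two_peaks():
    tri = ForceCurve(time=np.arange(5.0), force=[0, 250, 500, 250, 0])
    f, t = peak_force(tri)
    assert (f, t) == (500.0, 2.0)
    two = ForceCurve(time=np.arange(6.0), force=[0, 400, 100, 450, 100, 0])
    assert peak_force(two)[0] == 450.0  # global maximum wins


def test_peak_force_equals_sample_max_without_smoothing(rng):
    forces = rng.normal(500, 50, size=200)
    curve = ForceCurve(time=np.arange(200.0), force=forces)
    assert peak_force(curve, smoothing_window=1)[0] == forces.max()


def test_smoothed_peak_recovers_planted_peak(rng):
    t = np.arange(600.0)
    sigma = 5.0
    planted = 600.0 * np.exp(-((t - 300.0) ** 2) / (2 * 40.0**2))
    noisy = planted + rng.normal(0, sigma, size=t.size)
    f, t_peak = peak_force(ForceCurve(time=t, force=noisy), smoothing_window=11)
    assert abs(f - 600.0) < 3 * sigma
    assert abs(t_peak - 300.0) < 50


def test_aggregate_closed_form():
    stats = aggregate_ruptures([600.0, 610.0, 620.0])
    assert stats.mean == 610.0
    assert stats.sd == pytest.approx(10.0)
    assert stats.n == 3
    assert stats.mode_bin_center is None  # histogram needs n >= 5


def test_aggregate_single_value():
    stats = aggregate_ruptures([700.0])
    assert stats.mean == 700.0
    assert stats.sd is None


def test_aggregate_requires_data():
    with pytest.raises(ValueError):
        aggregate_ruptures([])


@settings(max_examples=100, deadline=None, derandomize=True)
@given(
    st.lists(st.floats(min_value=100, max_value=1000), min_size=5, max_size=80),
    st.sampled_from(["fd", "auto", 5, 12]),
)
def test_histogram_counts_conserve_n(values, bin_rule):
    stats = aggregate_ruptures(values, bin_rule=bin_rule)
    assert stats.histogram_counts.sum() == stats.n == len(values)
    assert min(values) - 1e-9 <= stats.mode_bin_center <= max(values) + 1e-9


def test_shift_and_scale_equivariance(rng):
    values = rng.normal(800, 100, size=50)
    base = aggregate_ruptures(values, bin_rule=10)
    shifted = aggregate_ruptures(values + 180.0, bin_rule=10)
    assert shifted.mean == pytest.approx(base.mean + 180.0)
    assert shifted.sd == pytest.approx(base.sd)
    assert shifted.mode_bin_center == pytest.approx(base.mode_bin_center + 180.0)
    scaled = aggregate_ruptures(values * 2.5, bin_rule=10)
    assert scaled.mean == pytest.approx(2.5 * base.mean)
    assert scaled.sd == pytest.approx(2.5 * base.sd)
    assert scaled.mode_bin_center == pytest.approx(2.5 * base.mode_bin_center)


def test_sampling_mean_within_three_standard_errors(rng):
    """50 draws at the published 2LLO-like moments land near the mean."""
    draws = rng.normal(828.0, 119.0, size=50)
    stats = aggregate_ruptures(draws)
    assert abs(stats.mean - 828.0) <= 3 * 119.0 / np.sqrt(50)


def test_compare_identical_samples_is_all_zero(rng):
    values = rng.normal(600, 40, size=30)
    a = aggregate_ruptures(values, bin_rule=8)
    cmp = compare_directions(a, a)
    assert cmp.mean_difference == 0.0
    assert cmp.mode_difference == 0.0
    assert cmp.bootstrap_interval[0] <= 0.0 <= cmp.bootstrap_interval[1]


def test_compare_shifted_copies(rng):
    values = rng.normal(613, 57, size=50)
    a = aggregate_ruptures(values + 180.0, bin_rule=10)
    b = aggregate_ruptures(values, bin_rule=10)
    cmp = compare_directions(a, b)
    assert cmp.mean_difference == pytest.approx(180.0)
    assert cmp.mode_difference == pytest.approx(180.0)
    assert cmp.effect_size > 0
    lo, hi = cmp.bootstrap_interval
    assert lo <= 180.0 <= hi


def test_compare_requires_minimum_n():
    a = aggregate_ruptures([1.0, 2.0, 3.0])
    with pytest.raises(ValueError):
        compare_directions(a, a)


def test_stats_json_round_trip(tmp_path, rng):
    stats = aggregate_ruptures(rng.normal(700, 50, size=20), label="RDM")
    path = stats.save(tmp_path / "stats.json")
    back = RuptureStats.load(path)
    assert back.label == "RDM"
    assert back.mean == stats.mean
    np.testing.assert_allclose(back.f_max_values, stats.f_max_values)
    np.testing.assert_array_equal(back.histogram_counts, stats.histogram_counts)
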