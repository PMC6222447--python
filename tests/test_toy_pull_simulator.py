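"""Brownian pulling simulator: landscape calculus, dynamics, oracles, Bell fit."""

import numpy as np
import pytest

from rdmpull.constants import COULOMB_KJ_NM_PER_E2
from rdmpull.toy_pull_simulator import (
    BellFit,
    PullSettings,
    ToyLandscapeParams,
    bell_fit,
    build_toy_landscape,
    dipole_stabilized_landscape,
    simulate_fmax_batch,
    simulate_pull,
    static_rupture_oracle,
)

Z = np.array([0.0, 0.0, 1.0])


# --- landscape ---------------------------------------------------------------


def test_gaussian_well_minimum_by_construction():
    L = build_toy_landscape(ToyLandscapeParams(well_depth=20.0, well_width=0.2))
    assert L.energy(np.zeros(3)) == pytest.approx(-20.0)
    assert L.energy(np.array([50.0, 0, 0])) == pytest.approx(0.0, abs=1e-12)


def test_coulomb_term_matches_hand_computation():
    L = build_toy_landscape(
        ToyLandscapeParams(
            well_depth=1.0,
            well_width=0.1,
            fixed_charges=(((0.0, 0.0, 0.0), 1.0),),
            ligand_charge=-1.0,
            dielectric=2.0,
        ),
        validate=False,
    )
    r = np.array([0.0, 0.0, 0.5])
    well = -1.0 * np.exp(-0.25 / (2 * 0.01))
    expected = well + COULOMB_KJ_NM_PER_E2 / 2.0 * (-1.0) / 0.5
    assert L.energy(r) == pytest.approx(expected, rel=1e-12)


@pytest.mark.parametrize(
    "params",
    [
        ToyLandscapeParams(well_depth=30, well_width=0.25),
        ToyLandscapeParams(well_depth=50, well_width=0.3, well_shape="ramp"),
        ToyLandscapeParams(
            well_depth=25,
            well_width=0.2,
            fixed_charges=(((0.3, 0.1, -0.4), 1.0), ((-0.2, 0.5, 0.3), -0.5)),
            ligand_charge=0.3,
            ligand_dipole=(0.1, -0.05, 0.2),
            softcore_nm=0.15,
        ),
        ToyLandscapeParams(
            well_depth=40,
            well_width=0.2,
            ligand_dipole=(0, 0, 0.5),
            field_strength=40.0,
        ),
    ],
    ids=["gaussian", "ramp", "charges+dipole", "field-slab"],
)
def test_gradient_consistent_with_finite_differences(params, rng):
    L = build_toy_landscape(params, validate=False)
    pts = rng.normal(scale=0.5, size=(100, 3))
    if L._cpos.size:
        d = np.linalg.norm(pts[:, None, :] - L._cpos, axis=-1)
        pts = pts[np.min(d, axis=-1) > 0.05]
    assert L.check_gradient(pts, rtol=1e-4) < 1e-4


def test_invalid_landscape_parameters_rejected():
    with pytest.raises(ValueError):
        ToyLandscapeParams(well_depth=-5)
    with pytest.raises(ValueError):
        ToyLandscapeParams(well_depth=np.nan)
    with pytest.raises(ValueError):
        ToyLandscapeParams(well_shape="volcano")


# --- static oracle -----------------------------------------------------------


def test_oracle_on_gaussian_well_closed_form():
    D, w = 20.0, 0.2
    L = build_toy_landscape(ToyLandscapeParams(well_depth=D, well_width=w))
    # max of dU/ds = D s / w^2 exp(-s^2/2w^2) is at s = w
    assert static_rupture_oracle(L, Z) == pytest.approx(
        D / w * np.exp(-0.5), rel=1e-4
    )


class _MorseLandscape:
    """Duck-typed landscape: Morse-style unbinding profile along any ray."""

    def __init__(self, depth, range_nm):
        self.depth = depth
        self.range_nm = range_nm
        self.params = ToyLandscapeParams(
            well_depth=depth, well_width=range_nm, well_position=(0, 0, 0)
        )

    def gradient(self, r):
        r = np.asarray(r, dtype=float)
        s = np.linalg.norm(r, axis=-1, keepdims=True)
        a = 1.0 / self.range_nm
        e = np.exp(-a * s)
        du = 2.0 * self.depth * a * (e - e**2)  # d/ds of D[(1-e)^2 - 1]
        return du * r / np.maximum(s, 1e-12)


def test_oracle_on_morse_well_matches_analytic_max_slope():
    D, a_range = 30.0, 0.25
    L = _MorseLandscape(D, a_range)
    # max slope of D[(1 - e^{-s/a})^2 - 1] is a*D/2 at s = a ln 2 (a = 1/range)
    assert static_rupture_oracle(L, Z, s_max=5.0) == pytest.approx(
        D / (2.0 * a_range), rel=1e-2
    )


class _FlatLandscape:
    params = ToyLandscapeParams(well_depth=1.0, well_width=0.1)

    def gradient(self, r):
        return np.zeros_like(np.asarray(r, dtype=float))


def test_oracle_on_flat_landscape_is_zero():
    assert static_rupture_oracle(_FlatLandscape(), Z) == pytest.approx(0.0, abs=1e-12)


# --- dynamics ----------------------------------------------------------------


def test_force_bookkeeping_identity():
    """F = k(vt - x) holds exactly at every logged sample."""
    L = build_toy_landscape(ToyLandscapeParams(well_depth=20, well_width=0.2))
    traj = simulate_pull(
        L, Z, v=1e-2, k=100.0, temperature=310.0, dt=1e-3, seed=4,
        max_time=100.0, settings=PullSettings(gamma=50.0),
    )
    expected = traj.spring_constant_k * (
        traj.pull_speed_v * traj.times - traj.displacement
    )
    np.testing.assert_allclose(traj.force, expected, atol=1e-9)


def test_zero_temperature_flat_landscape_tracks_anchor():
    flat = build_toy_landscape(
        ToyLandscapeParams(well_depth=1e-9, well_width=1.0), validate=False
    )
    settings = PullSettings(gamma=50.0)
    traj = simulate_pull(
        flat, Z, v=1e-3, k=100.0, temperature=0.0, dt=1e-2, seed=0,
        max_time=500.0, settings=settings,
    )
    # steady-state lag force is gamma*v, essentially zero on the well scale
    assert np.max(np.abs(traj.force)) < 1.0
    assert not traj.ruptured


def test_zero_temperature_quasistatic_fmax_matches_oracle():
    L = build_toy_landscape(ToyLandscapeParams(well_depth=20, well_width=0.2))
    oracle = static_rupture_oracle(L, Z)
    out = simulate_fmax_batch(
        L, Z, v=1e-4, k=500.0, temperature=0.0, dt=5e-4, seeds=[0],
        max_time=1e4, settings=PullSettings(gamma=20.0),
    )
    assert out["ruptured"][0]
    assert out["f_max"][0] == pytest.approx(oracle, rel=0.02)


def test_fixed_seed_reproducibility():
    L = build_toy_landscape(ToyLandscapeParams(well_depth=25, well_width=0.2))
    kwargs = dict(
        v=5e-3, k=100.0, temperature=310.0, dt=1e-3, seed=11, max_time=50.0,
        settings=PullSettings(gamma=50.0),
    )
    a = simulate_pull(L, Z, **kwargs)
    b = simulate_pull(L, Z, **kwargs)
    np.testing.assert_array_equal(a.positions, b.positions)
    np.testing.assert_array_equal(a.force, b.force)


def test_batch_kernel_agrees_with_python_path_at_zero_temperature():
    """The compiled batch kernel and the recording integrator are the same
    dynamical system; with no noise they produce the same rupture force."""
    L = build_toy_landscape(ToyLandscapeParams(well_depth=20, well_width=0.2))
    settings = PullSettings(gamma=20.0)
    kwargs = dict(v=5e-3, k=200.0, temperature=0.0, dt=1e-3, max_time=500.0)
    traj = simulate_pull(L, Z, seed=0, settings=settings, **kwargs)
    batch = simulate_fmax_batch(L, Z, seeds=[0], settings=settings, **kwargs)
    assert batch["f_max"][0] == pytest.approx(traj.f_max, rel=1e-9)
    assert bool(batch["ruptured"][0]) == traj.ruptured


def test_unstable_timestep_is_rejected():
    L = build_toy_landscape(ToyLandscapeParams(well_depth=20, well_width=0.2))
    with pytest.raises(ValueError, match="unstable"):
        simulate_pull(
            L, Z, v=1e-3, k=1000.0, temperature=300.0, dt=0.1, seed=0,
            max_time=10.0, settings=PullSettings(gamma=50.0),
        )


def test_non_unit_direction_rejected():
    L = build_toy_landscape(ToyLandscapeParams(well_depth=20, well_width=0.2))
    with pytest.raises(ValueError, match="unit"):
        simulate_pull(
            L, (0, 0, 2.0), v=1e-3, k=100.0, temperature=0.0, dt=1e-3,
            seed=0, max_time=10.0,
        )


# --- Bell fit ----------------------------------------------------------------


def test_bell_fit_exact_line():
    speeds = [1e-5, 1e-4, 1e-3, 1e-2]
    pts = [(v, 50.0 * np.log(v) + 300.0) for v in speeds]
    fit = bell_fit(pts, temperature=310.0)
    assert fit.slope == pytest.approx(50.0, rel=1e-12)
    assert fit.intercept == pytest.approx(300.0, rel=1e-9)
    assert fit.r_squared == pytest.approx(1.0, abs=1e-12)
    assert fit.x_beta_nm == pytest.approx(0.0083144626 * 310.0 / 50.0, rel=1e-4)


def test_bell_fit_preconditions():
    with pytest.raises(ValueError, match="at least 3"):
        bell_fit([(1e-4, 10.0), (1e-3, 20.0)])
    with pytest.raises(ValueError, match="two decades"):
        bell_fit([(1e-4, 10.0), (2e-4, 12.0), (4e-4, 14.0)])
    with pytest.raises(ValueError, match="positive"):
        bell_fit([(-1e-4, 10.0), (1e-3, 12.0), (1e-1, 14.0)])


# --- direction dependence (landscape level) ----------------------------------


def test_field_slab_makes_aligned_pulling_statically_harder():
    L = dipole_stabilized_landscape(Z)
    aligned = static_rupture_oracle(L, Z)
    orthogonal = static_rupture_oracle(L, np.array([1.0, 0.0, 0.0]))
    assert aligned > orthogonal * 1.2
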