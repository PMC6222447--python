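"""Desk-scale Brownian-dynamics simulator of constant-velocity spring pulling.

A single bead (the "ligand") moves in an analytic binding landscape — a
Gaussian binding well plus optional Coulomb and dipole-field electrostatics —
while a harmonic spring of stiffness k, anchored to a point moving at
constant speed v along a fixed unit direction, drags it out.  The logged
spring force is exactly F = k(vt - x), with x the bead displacement along
the pulling direction, so force-extension curves, rupture-force histograms
and Bell (log-loading-rate) analyses can be exercised end to end without an
MD engine.

Integration is overdamped (no inertia): dr = F/gamma dt + sqrt(2 kB T dt /
gamma) eta, appropriate for the high-friction regime.  Units are nm, ps,
kJ/mol, e, K throughout, so forces are in kJ/mol/nm like GROMACS output.

The model is a mechanistic toy: it reproduces the phenomenology of
force-spectroscopy pulling (single rupture peak, log(v) force scaling,
direction-dependent stability when an electrostatic term is anisotropic),
not the absolute forces of any all-atom system.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
from scipy import stats as _stats

from .constants import COULOMB_KJ_NM_PER_E2, KB_KJ_PER_MOL_K

__all__ = [
    "ToyLandscapeParams",
    "ToyLandscape",
    "PullTrajectory",
    "PullSettings",
    "build_toy_landscape",
    "simulate_pull",
    "simulate_fmax_batch",
    "static_rupture_oracle",
    "bell_fit",
    "BellFit",
]


@dataclasses.dataclass(frozen=True)
class ToyLandscapeParams:
    """Parameters of the analytic binding landscape.

    Two well shapes are available (s = distance from the well position):

    * ``"gaussian"``: U = -D exp(-s^2 / 2 w^2).  A soft, "ductile" well —
      the maximum restoring force sits at the inflection s = w, but the
      distance between the force-tilted minimum and barrier shrinks and
      stretches with the applied force.
    * ``"ramp"``: a flat-bottomed well of depth D climbing linearly back to
      zero over the width w, with corners smoothed over ``smoothing_nm``
      (default w/20).  A "brittle" well: the escape barrier sits at the
      outer corner regardless of force, so its barrier distance — the
      quantity a Bell analysis estimates — is the programmed width w for
      any force comfortably below the critical slope D/w.

    ``fixed_charges`` are immobile point charges (position nm, charge e);
    the bead may carry a net charge and/or a rigidly attached point dipole
    (e nm) that couples to the field of the fixed charges.

    The optional interface-field slab models the electric double layer of a
    binding interface: a field along ``field_normal`` of strength
    ``field_strength`` (kJ/mol/nm per e, i.e. force per unit charge),
    Gaussian-localised within ``field_thickness_nm`` along the normal and
    ``field_width_nm`` laterally.  A ligand dipole aligned with the normal
    is stabilised inside the slab; unbinding across the slab (along the
    field) climbs the full coupling over the short thickness, while
    unbinding sideways leaves it over the long lateral width.
    """

    well_depth: float = 20.0  # kJ/mol
    well_width: float = 0.2  # nm
    well_position: tuple[float, float, float] = (0.0, 0.0, 0.0)
    well_shape: str = "gaussian"
    smoothing_nm: float | None = None  # ramp corner scale; default w/20
    fixed_charges: tuple[tuple[tuple[float, float, float], float], ...] = ()
    ligand_charge: float = 0.0  # e
    ligand_dipole: tuple[float, float, float] = (0.0, 0.0, 0.0)  # e nm
    dielectric: float = 1.0
    #: soft-core length (nm): electrostatic distances are replaced by
    #: sqrt(d^2 + softcore^2), keeping the toy landscape bounded near the
    #: point charges (0 recovers bare Coulomb).
    softcore_nm: float = 0.0
    # interface-field slab (active when field_strength != 0)
    field_normal: tuple[float, float, float] = (0.0, 0.0, 1.0)
    field_strength: float = 0.0  # kJ/mol/nm/e at the slab centre
    field_thickness_nm: float = 0.15
    field_width_nm: float = 1.0

    def __post_init__(self) -> None:
        vals = [
            self.well_depth,
            self.well_width,
            self.ligand_charge,
            self.dielectric,
            *self.well_position,
            *self.ligand_dipole,
        ] + [x for pos, q in self.fixed_charges for x in (*pos, q)]
        if not np.all(np.isfinite(vals)):
            raise ValueError("non-finite landscape parameter")
        if self.well_depth <= 0 or self.well_width <= 0:
            raise ValueError("well depth and width must be positive")
        if self.well_shape not in ("gaussian", "ramp"):
            raise ValueError(f"unknown well shape {self.well_shape!r}")
        if self.smoothing_nm is not None and self.smoothing_nm <= 0:
            raise ValueError("smoothing_nm must be positive")
        if self.softcore_nm < 0:
            raise ValueError("softcore_nm must be non-negative")
        if self.field_thickness_nm <= 0 or self.field_width_nm <= 0:
            raise ValueError("field slab dimensions must be positive")
        if self.field_strength != 0.0 and np.linalg.norm(self.field_normal) < 1e-12:
            raise ValueError("field_normal must be non-zero")
        if self.dielectric <= 0:
            raise ValueError("dielectric must be positive")

    @property
    def smoothing(self) -> float:
        return (
            self.smoothing_nm
            if self.smoothing_nm is not None
            else self.well_width / 20.0
        )


class ToyLandscape:
    """Evaluators U(r) [kJ/mol] and grad U(r) [kJ/mol/nm], vectorised."""

    def __init__(self, params: ToyLandscapeParams):
        self.params = params
        self._r0 = np.asarray(params.well_position, dtype=float)
        self._mu = np.asarray(params.ligand_dipole, dtype=float)
        self._cpos = np.array(
            [pos for pos, _ in params.fixed_charges], dtype=float
        ).reshape(-1, 3)
        self._cq = np.array([q for _, q in params.fixed_charges], dtype=float)
        self._f = COULOMB_KJ_NM_PER_E2 / params.dielectric
        n = np.asarray(params.field_normal, dtype=float)
        self._n = n / np.linalg.norm(n) if np.linalg.norm(n) > 0 else n
        # dipole-slab coupling energy at the slab centre, kJ/mol
        self._slab_c = float(self._mu @ self._n) * params.field_strength

    @property
    def barrier_distance_nm(self) -> float:
        """Distance from the well minimum to the point of maximum restoring
        force of the well term: the inflection (= width) of the Gaussian,
        the outer corner (= width) of the ramp."""
        return self.params.well_width

    @property
    def max_curvature(self) -> float:
        """Upper bound on |U''| of the well term, for integrator stability."""
        p = self.params
        if p.well_shape == "ramp":
            # steepest force change happens over the corner smoothing scale
            well = p.well_depth / p.well_width * 0.25 / p.smoothing
        else:
            well = p.well_depth / p.well_width**2
        return well + abs(self._slab_c) / p.field_thickness_nm**2

    def _well_energy_radial(self, s2: np.ndarray) -> np.ndarray:
        """Well energy as a function of squared distance from the minimum."""
        p = self.params
        if p.well_shape == "ramp":
            eps = p.smoothing
            s = np.sqrt(s2 + eps * eps)
            ramp = eps * (
                np.logaddexp(0.0, s / eps) - np.logaddexp(0.0, (s - p.well_width) / eps)
            )
            return -p.well_depth + p.well_depth / p.well_width * ramp
        w2 = p.well_width**2
        return -p.well_depth * np.exp(-s2 / (2.0 * w2))

    def _well_gradient_prefactor(self, s2: np.ndarray) -> np.ndarray:
        """dU/ds / s for the well term, so grad U = prefactor * (r - r0)."""
        p = self.params
        if p.well_shape == "ramp":
            eps = p.smoothing
            s = np.sqrt(s2 + eps * eps)
            sigmoid = lambda x: 0.5 * (1.0 + np.tanh(0.5 * x))  # noqa: E731
            dl = sigmoid(s / eps) - sigmoid((s - p.well_width) / eps)
            return p.well_depth / p.well_width * dl / s
        w2 = p.well_width**2
        return p.well_depth / w2 * np.exp(-s2 / (2.0 * w2))

    def energy(self, r: np.ndarray) -> np.ndarray:
        r = np.asarray(r, dtype=float)
        dr = r - self._r0
        s2 = np.sum(dr * dr, axis=-1)
        u = self._well_energy_radial(s2)
        if self._cq.size:
            dv = r[..., None, :] - self._cpos  # (..., m, 3)
            sc = self.params.softcore_nm
            d = np.sqrt(np.sum(dv * dv, axis=-1) + sc * sc)
            if self.params.ligand_charge != 0.0:
                u = u + self._f * self.params.ligand_charge * np.sum(
                    self._cq / d, axis=-1
                )
            if np.any(self._mu):
                # U = -mu . E, E = f q (r-c)/d^3
                proj = np.sum(dv * self._mu, axis=-1)
                u = u - self._f * np.sum(self._cq * proj / d**3, axis=-1)
        if self._slab_c != 0.0:
            zn = dr @ self._n
            rho2 = np.sum(dr * dr, axis=-1) - zn * zn
            p = self.params
            u = u - self._slab_c * np.exp(
                -(zn * zn) / (2.0 * p.field_thickness_nm**2)
                - rho2 / (2.0 * p.field_width_nm**2)
            )
        return u

    def gradient(self, r: np.ndarray) -> np.ndarray:
        r = np.asarray(r, dtype=float)
        dr = r - self._r0
        s2 = np.sum(dr * dr, axis=-1, keepdims=True)
        g = self._well_gradient_prefactor(s2) * dr
        if self._cq.size:
            dv = r[..., None, :] - self._cpos
            sc = self.params.softcore_nm
            d = np.sqrt(np.sum(dv * dv, axis=-1) + sc * sc)
            if self.params.ligand_charge != 0.0:
                g = g - self._f * self.params.ligand_charge * np.sum(
                    (self._cq / d**3)[..., None] * dv, axis=-2
                )
            if np.any(self._mu):
                proj = np.sum(dv * self._mu, axis=-1)  # (..., m)
                g = g - self._f * (
                    np.sum((self._cq / d**3), axis=-1)[..., None] * self._mu
                    - 3.0
                    * np.sum(
                        (self._cq * proj / d**5)[..., None] * dv, axis=-2
                    )
                )
        if self._slab_c != 0.0:
            p = self.params
            zn = dr @ self._n
            perp = dr - zn[..., None] * self._n
            rho2 = np.sum(perp * perp, axis=-1)
            x = np.exp(
                -(zn * zn) / (2.0 * p.field_thickness_nm**2)
                - rho2 / (2.0 * p.field_width_nm**2)
            )
            g = g + (self._slab_c * x)[..., None] * (
                (zn / p.field_thickness_nm**2)[..., None] * self._n
                + perp / p.field_width_nm**2
            )
        return g

    def check_gradient(
        self, points: np.ndarray, h: float = 1e-5, rtol: float = 1e-4
    ) -> float:
        """Max relative error of the analytic gradient vs central finite
        differences of the energy at the given points; raises if > rtol."""
        points = np.atleast_2d(np.asarray(points, dtype=float))
        num = np.empty_like(points)
        for k in range(3):
            e = np.zeros(3)
            e[k] = h
            num[:, k] = (self.energy(points + e) - self.energy(points - e)) / (
                2.0 * h
            )
        ana = self.gradient(points)
        # floor the scale at a tiny fraction of the well's characteristic
        # force so finite-difference cancellation noise in flat regions
        # does not register as disagreement
        floor = 1e-6 * self.params.well_depth / self.params.well_width
        scale = np.maximum(np.linalg.norm(ana, axis=-1), floor)
        err = float(np.max(np.linalg.norm(ana - num, axis=-1) / scale))
        if err > rtol:
            raise ValueError(
                f"analytic gradient disagrees with finite differences "
                f"(max rel err {err:.2e})"
            )
        return err


def build_toy_landscape(
    params: ToyLandscapeParams, validate: bool = True
) -> ToyLandscape:
    """Construct a landscape; optionally self-check grad U against finite
    differences on a deterministic sample around the well."""
    landscape = ToyLandscape(params)
    if validate:
        rng = np.random.default_rng(0)
        pts = np.asarray(params.well_position) + rng.normal(
            scale=2.0 * params.well_width, size=(32, 3)
        )
        # keep clear of point-charge singularities
        if landscape._cpos.size:
            d = np.linalg.norm(pts[:, None, :] - landscape._cpos, axis=-1)
            pts = pts[np.min(d, axis=-1) > 0.1]
        landscape.check_gradient(pts)
    return landscape


@dataclasses.dataclass(frozen=True)
class PullSettings:
    """Numerical settings of the Brownian integrator.

    gamma is the friction coefficient in kJ mol^-1 ps nm^-2; the stability
    bound dt * k_total / gamma < 0.1 is enforced (k_total includes the well
    curvature D/w^2).  Forces are smoothed with an exponential moving
    average of time constant smooth_tau_ps both for rupture detection and
    for the reported F_max; rupture is declared when the smoothed force has
    stayed below max(rupture_fraction * running peak, noise floor) for
    smooth_tau_ps, after the peak has cleared the noise floor.
    """

    gamma: float = 50.0
    sample_every: int = 1
    smooth_tau_ps: float | None = None  # default: 20 * gamma / k_total
    rupture_fraction: float = 0.10
    min_peak: float | None = None  # default: 2 * detection noise floor
    #: the force-drop criterion is armed only once the bead displacement
    #: along the pulling direction exceeds this (None: 4 well widths) —
    #: a bead still inside the well cannot have ruptured.
    escape_distance_nm: float | None = None

    def resolved(
        self, k: float, temperature: float, dt: float, well_curvature: float
    ) -> tuple[float, float, float]:
        """(smooth_tau, noise_floor, min_peak) for the given run."""
        k_tot = k + well_curvature
        tau_c = self.gamma / k_tot  # bead relaxation time in the trap
        smooth_tau = (
            self.smooth_tau_ps if self.smooth_tau_ps is not None else 20.0 * tau_c
        )
        sigma_f = k * np.sqrt(KB_KJ_PER_MOL_K * temperature / k_tot)
        # EMA over smooth_tau of noise correlated over tau_c
        sigma_ema = sigma_f * np.sqrt(tau_c / max(smooth_tau, tau_c))
        noise_floor = 3.0 * sigma_ema
        min_peak = self.min_peak if self.min_peak is not None else 2.0 * noise_floor
        return smooth_tau, noise_floor, min_peak


@dataclasses.dataclass
class PullTrajectory:
    """One logged pulling trajectory (times ps, lengths nm, force kJ/mol/nm)."""

    times: np.ndarray
    positions: np.ndarray  # (n, 3) bead positions
    anchor_positions: np.ndarray  # (n, 3) spring anchor positions
    force: np.ndarray  # spring force k(vt - x) along the pulling direction
    smoothed_force: np.ndarray
    direction: np.ndarray
    spring_constant_k: float
    pull_speed_v: float
    ruptured: bool
    rupture_time: float | None

    @property
    def displacement(self) -> np.ndarray:
        """Bead displacement x along the pulling direction."""
        return (self.positions - self.positions[0]) @ self.direction

    @property
    def f_max(self) -> float:
        return float(np.max(self.smoothed_force))


def _stability_check(dt: float, k: float, gamma: float, curvature: float) -> None:
    k_tot = k + curvature
    if dt * k_tot / gamma >= 0.1:
        raise ValueError(
            f"unstable integration: dt*k_total/gamma = {dt * k_tot / gamma:.3g} "
            f">= 0.1; reduce dt below {0.1 * gamma / k_tot:.3g} ps"
        )


def _run_batch(
    landscape: ToyLandscape,
    direction: np.ndarray,
    v: float,
    k: float,
    temperature: float,
    dt: float,
    seeds: Sequence[int],
    max_time: float,
    settings: PullSettings,
    record: bool,
):
    """Vectorised overdamped Langevin kernel shared by the single-trajectory
    and batch entry points.  Returns per-trajectory summaries and, when
    ``record`` is true, the full series of trajectory 0."""
    direction = np.asarray(direction, dtype=float)
    if abs(np.linalg.norm(direction) - 1.0) > 1e-9:
        raise ValueError("pulling direction must be a unit vector")
    if v <= 0 or k <= 0 or dt <= 0:
        raise ValueError("v, k and dt must be positive")
    curvature = landscape.max_curvature
    _stability_check(dt, k, settings.gamma, curvature)
    smooth_tau, noise_floor, min_peak = settings.resolved(
        k, temperature, dt, curvature
    )
    escape = (
        settings.escape_distance_nm
        if settings.escape_distance_nm is not None
        else 4.0 * landscape.params.well_width
    )
    alpha = min(1.0, dt / smooth_tau)
    confirm_steps = max(1, int(round(smooth_tau / dt)))

    n = len(seeds)
    rngs = [np.random.default_rng(int(s)) for s in seeds]
    r0 = np.asarray(landscape.params.well_position, dtype=float)
    r = np.tile(r0, (n, 1))
    gamma = settings.gamma
    kbt = KB_KJ_PER_MOL_K * temperature
    noise_scale = np.sqrt(2.0 * kbt * dt / gamma)

    n_steps = int(np.ceil(max_time / dt))
    noise_block_size = 1024  # per-stream normals drawn in blocks for speed
    noise_blocks = None
    noise_cursor = noise_block_size
    ema = np.zeros(n)
    peak = np.zeros(n)
    fmax = np.zeros(n)
    below = np.zeros(n, dtype=int)
    ruptured = np.zeros(n, dtype=bool)
    rupture_time = np.full(n, np.nan)
    active = np.ones(n, dtype=bool)

    rec_t, rec_r, rec_anchor, rec_f, rec_ema = [], [], [], [], []

    t = 0.0
    for step in range(n_steps + 1):
        x = (r - r0) @ direction
        f_spring = k * (v * t - x)  # identity F = k(vt - x)
        if record:
            rec_t.append(t)
            rec_r.append(r[0].copy())
            rec_anchor.append(r0 + (v * t) * direction)
            rec_f.append(f_spring[0])
        ema = ema + alpha * (f_spring - ema)
        if record:
            rec_ema.append(ema[0])
        peak = np.maximum(peak, ema)
        fmax = np.where(active, np.maximum(fmax, ema), fmax)

        threshold = np.maximum(settings.rupture_fraction * peak, noise_floor)
        dropping = (ema < threshold) & (peak > min_peak) & (x > escape) & active
        below = np.where(dropping, below + 1, 0)
        newly = below >= confirm_steps
        if np.any(newly & active):
            idx = newly & active
            ruptured[idx] = True
            rupture_time[idx] = t
            active[idx] = False
        if not np.any(active) and not record:
            break
        if record and ruptured[0]:
            break
        if step == n_steps:
            break

        grad = landscape.gradient(r)
        force_total = -grad + f_spring[:, None] * direction
        if temperature > 0:
            if noise_cursor >= noise_block_size:
                noise_blocks = np.stack(
                    [rng.normal(size=(noise_block_size, 3)) for rng in rngs],
                    axis=1,
                )
                noise_cursor = 0
            noise = noise_blocks[noise_cursor]
            noise_cursor += 1
            r = r + force_total * dt / gamma + noise_scale * noise
        else:
            r = r + force_total * dt / gamma
        t += dt

    summaries = {
        "f_max": fmax,
        "ruptured": ruptured,
        "rupture_time": rupture_time,
    }
    if record:
        stride = settings.sample_every
        traj = PullTrajectory(
            times=np.asarray(rec_t)[::stride],
            positions=np.asarray(rec_r)[::stride],
            anchor_positions=np.asarray(rec_anchor)[::stride],
            force=np.asarray(rec_f)[::stride],
            smoothed_force=np.asarray(rec_ema)[::stride],
            direction=direction,
            spring_constant_k=k,
            pull_speed_v=v,
            ruptured=bool(ruptured[0]),
            rupture_time=float(rupture_time[0]) if ruptured[0] else None,
        )
        return summaries, traj
    return summaries, None


def simulate_pull(
    landscape: ToyLandscape,
    direction: Sequence[float],
    v: float,
    k: float,
    temperature: float,
    dt: float,
    seed: int,
    max_time: float,
    settings: PullSettings | None = None,
) -> PullTrajectory:
    """Run one constant-velocity pulling trajectory and log the full series.

    Deterministic for a fixed seed; terminates at ``max_time`` ps or on
    rupture (sustained drop of the smoothed force below the running-peak
    fraction configured in ``settings``).
    """
    settings = settings or PullSettings()
    _, traj = _run_batch(
        landscape,
        np.asarray(direction, dtype=float),
        v,
        k,
        temperature,
        dt,
        [seed],
        max_time,
        settings,
        record=True,
    )
    return traj


def simulate_fmax_batch(
    landscape: ToyLandscape,
    direction: Sequence[float],
    v: float,
    k: float,
    temperature: float,
    dt: float,
    seeds: Sequence[int],
    max_time: float,
    settings: PullSettings | None = None,
) -> dict[str, np.ndarray]:
    """Rupture-force summaries (f_max, ruptured, rupture_time) for many seeds.

    Runs the compiled inner loop (same stepping rule and rupture detector as
    :func:`simulate_pull`, cross-checked at T = 0 in the tests), one
    independent RNG stream per seed.  Seeds must fit in 32 bits.
    """
    from ._bd_kernel import pull_fmax_kernel  # deferred: numba compile cost

    settings = settings or PullSettings()
    direction = np.asarray(direction, dtype=float)
    if abs(np.linalg.norm(direction) - 1.0) > 1e-9:
        raise ValueError("pulling direction must be a unit vector")
    if v <= 0 or k <= 0 or dt <= 0:
        raise ValueError("v, k and dt must be positive")
    p = landscape.params
    curvature = landscape.max_curvature
    _stability_check(dt, k, settings.gamma, curvature)
    smooth_tau, noise_floor, min_peak = settings.resolved(
        k, temperature, dt, curvature
    )
    seeds_arr = np.asarray(list(seeds), dtype=np.uint32)
    if len(seeds_arr) != len(list(seeds)):
        raise ValueError("empty seed list")
    fmax, ruptured, rupture_time = pull_fmax_kernel(
        seeds_arr,
        np.asarray(p.well_position, dtype=float),
        1 if p.well_shape == "ramp" else 0,
        float(p.well_depth),
        float(p.well_width),
        float(p.smoothing),
        landscape._cpos,
        landscape._cq,
        float(p.ligand_charge),
        np.asarray(p.ligand_dipole, dtype=float),
        float(landscape._f),
        float(p.softcore_nm**2),
        float(landscape._slab_c),
        landscape._n,
        float(p.field_thickness_nm**2),
        float(p.field_width_nm**2),
        direction,
        float(v),
        float(k),
        float(KB_KJ_PER_MOL_K * temperature),
        float(dt),
        float(settings.gamma),
        int(np.ceil(max_time / dt)),
        float(min(1.0, dt / smooth_tau)),
        int(max(1, round(smooth_tau / dt))),
        float(settings.rupture_fraction),
        float(noise_floor),
        float(min_peak),
        float(
            settings.escape_distance_nm
            if settings.escape_distance_nm is not None
            else 4.0 * p.well_width
        ),
    )
    return {"f_max": fmax, "ruptured": ruptured, "rupture_time": rupture_time}


def rupture_anchor_travel(
    landscape: ToyLandscape, direction: Sequence[float], k: float
) -> float:
    """Anchor displacement (nm) by which rupture is guaranteed even for a
    bead stuck at the well: static rupture force / k plus four well widths."""
    f_static = static_rupture_oracle(landscape, direction)
    return f_static / k + 4.0 * landscape.params.well_width


def bell_sweep(
    landscape: ToyLandscape,
    direction: Sequence[float],
    speeds: Sequence[float],
    n_seeds: int,
    k: float,
    temperature: float,
    dt: float,
    base_seed: int = 1,
    settings: PullSettings | None = None,
) -> list[dict]:
    """Mean rupture force at each pulling speed, n_seeds trajectories each.

    Per-trajectory seeds are base_seed + index, continuing across speeds so
    every trajectory in the sweep has a distinct stream.  max_time at each
    speed is set from the static rupture force so every trajectory ends in
    rupture or a fully stretched spring.
    """
    results = []
    offset = 0
    for v in sorted(speeds):
        seeds = [base_seed + offset + i for i in range(n_seeds)]
        offset += n_seeds
        max_time = rupture_anchor_travel(landscape, direction, k) / v
        out = simulate_fmax_batch(
            landscape, direction, v, k, temperature, dt, seeds, max_time, settings
        )
        results.append(
            {
                "speed": float(v),
                "mean_f_max": float(out["f_max"].mean()),
                "sd_f_max": float(out["f_max"].std(ddof=1)),
                "f_max": out["f_max"],
                "rupture_fraction_of_runs": float(out["ruptured"].mean()),
            }
        )
    return results


def bell_benchmark(
    base_seed: int = 1,
    n_seeds: int = 30,
    speeds: Sequence[float] = (1e-5, 1e-4, 1e-3),
) -> dict:
    """Canonical loading-rate sweep on a brittle well of known barrier distance.

    The well is a smoothed linear ramp (depth 50 kJ/mol ~ 19 kBT at 310 K,
    width 0.3 nm), pulled with a soft spring (k = 20 kJ/mol/nm^2) so the
    load is force-like rather than position-clamped; the three speeds span
    two decades well below the critical force D/w, i.e. inside the
    thermally activated regime where the rupture force grows linearly in
    ln(v) with slope kB*T / barrier distance.  Returns the per-speed means,
    the Bell fit, and the programmed barrier distance (0.3 nm).
    """
    landscape = build_toy_landscape(
        ToyLandscapeParams(well_depth=50.0, well_width=0.3, well_shape="ramp")
    )
    settings = PullSettings(gamma=200.0)
    k = 20.0
    dt = 0.05 * settings.gamma / (k + landscape.max_curvature)  # half the bound
    results = bell_sweep(
        landscape,
        (0.0, 0.0, 1.0),
        speeds,
        n_seeds,
        k=k,
        temperature=310.0,
        dt=dt,
        base_seed=base_seed,
        settings=settings,
    )
    fit = bell_fit(
        [(r["speed"], r["mean_f_max"]) for r in results], temperature=310.0
    )
    return {
        "results": results,
        "fit": fit,
        "programmed_barrier_distance_nm": landscape.barrier_distance_nm,
    }


def direction_dependence_benchmark(
    base_seed: int = 1,
    n_per_batch: int = 20,
    n_batches: int = 3,
    v: float = 1e-3,
    k: float = 100.0,
    temperature: float = 310.0,
) -> dict:
    """Rupture forces pulled along vs orthogonal to the interface field.

    Runs ``n_batches`` independent seed batches on the default
    dipole-stabilised landscape and reports per-batch mean rupture forces
    for the field-aligned and an orthogonal pulling direction.  The
    qualitative claim under test is that the aligned mean exceeds the
    orthogonal mean with a stable sign across batches.
    """
    landscape = dipole_stabilized_landscape((0.0, 0.0, 1.0))
    settings = PullSettings(gamma=50.0)
    dt = 0.05 * settings.gamma / (k + landscape.max_curvature)
    out: dict = {"aligned": [], "orthogonal": []}
    for name, direction in (
        ("aligned", (0.0, 0.0, 1.0)),
        ("orthogonal", (1.0, 0.0, 0.0)),
    ):
        for batch in range(n_batches):
            seeds = [base_seed + 1000 * batch + i for i in range(n_per_batch)]
            res = simulate_fmax_batch(
                landscape,
                direction,
                v=v,
                k=k,
                temperature=temperature,
                dt=dt,
                seeds=seeds,
                max_time=rupture_anchor_travel(landscape, direction, k) / v,
                settings=settings,
            )
            out[name].append(res["f_max"])
    out["aligned_means"] = [float(b.mean()) for b in out["aligned"]]
    out["orthogonal_means"] = [float(b.mean()) for b in out["orthogonal"]]
    out["sign_consistent"] = all(
        a > o for a, o in zip(out["aligned_means"], out["orthogonal_means"])
    )
    return out


def dipole_stabilized_landscape(
    field_direction: Sequence[float],
    well_depth: float = 40.0,
    well_width: float = 0.2,
    dipole_e_nm: float = 0.5,
    field_strength: float = 40.0,
    field_thickness_nm: float = 0.15,
    field_width_nm: float = 1.0,
) -> ToyLandscape:
    """Binding well stabilised by the ligand dipole in an interface field.

    The bead carries a dipole along ``field_direction`` and sits in the
    interface-field slab oriented perpendicular to that direction (the
    double-layer field of a quasi-planar binding interface).  Unbinding
    along the field direction has to break the dipole-field interaction
    across the thin slab — a large force over a short distance — whereas
    unbinding orthogonally slides the dipole out sideways over the slab's
    long lateral extent.  Rupture forces along the field direction are
    therefore systematically larger: the toy analogue of the extra
    mechanical stability seen when a complex is pulled apart along its
    interface dipole rather than along an arbitrary (COM) direction.
    """
    d = np.asarray(field_direction, dtype=float)
    d = d / np.linalg.norm(d)
    params = ToyLandscapeParams(
        well_depth=well_depth,
        well_width=well_width,
        well_position=(0.0, 0.0, 0.0),
        ligand_dipole=tuple(dipole_e_nm * d),
        field_normal=tuple(d),
        field_strength=field_strength,
        field_thickness_nm=field_thickness_nm,
        field_width_nm=field_width_nm,
    )
    return build_toy_landscape(params)


def static_rupture_oracle(
    landscape: ToyLandscape,
    direction: Sequence[float],
    s_max: float = 3.0,
    n_grid: int = 4096,
    rtol: float = 1e-3,
    max_refine: int = 6,
) -> float:
    """Zero-temperature brute-force rupture force, kJ/mol/nm.

    Scans the restoring-force component grad U . direction on a dense 1-D
    grid along the pulling path from the well minimum and returns its
    maximum; the grid is refined until the answer is converged to ``rtol``.
    """
    direction = np.asarray(direction, dtype=float)
    direction = direction / np.linalg.norm(direction)
    r0 = np.asarray(landscape.params.well_position, dtype=float)

    def scan(n: int) -> float:
        s = np.linspace(0.0, s_max, n)[:, None]
        pts = r0 + s * direction
        resist = landscape.gradient(pts) @ direction
        return float(np.max(resist))

    value = scan(n_grid)
    for _ in range(max_refine):
        n_grid *= 2
        refined = scan(n_grid)
        if abs(refined - value) <= rtol * max(abs(refined), 1e-12):
            return refined
        value = refined
    raise ValueError(
        "rupture-force scan did not converge; grid too coarse or path escapes "
        "the sampled range"
    )


@dataclasses.dataclass(frozen=True)
class BellFit:
    """Least-squares line F_max = slope * ln(v) + intercept.

    Under the Bell picture the slope is kB*T / x_beta, so x_beta (the
    distance from the bound state to the barrier along the pulling
    coordinate) is estimated as kB*T / slope.
    """

    slope: float  # kJ/mol/nm per ln(nm/ps)
    intercept: float
    x_beta_nm: float
    r_squared: float
    temperature: float


def bell_fit(
    fmax_by_speed: Sequence[tuple[float, float]],
    temperature: float = 310.0,
) -> BellFit:
    """Fit mean rupture force against ln(pulling speed).

    Requires at least 3 speeds spanning at least two decades.
    """
    if len(fmax_by_speed) < 3:
        raise ValueError("Bell fit needs at least 3 (speed, F_max) points")
    v = np.array([p[0] for p in fmax_by_speed], dtype=float)
    f = np.array([p[1] for p in fmax_by_speed], dtype=float)
    if np.any(v <= 0):
        raise ValueError("pulling speeds must be positive")
    if np.log10(v.max() / v.min()) < 2.0 - 1e-9:
        raise ValueError("speeds must span at least two decades")
    res = _stats.linregress(np.log(v), f)
    slope = float(res.slope)
    if slope <= 0:
        x_beta = float("nan")
    else:
        x_beta = KB_KJ_PER_MOL_K * temperature / slope
    return BellFit(
        slope=slope,
        intercept=float(res.intercept),
        x_beta_nm=x_beta,
        r_squared=float(res.rvalue**2),
        temperature=temperature,
    )
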