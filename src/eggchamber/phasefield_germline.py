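"""Two-phase field model of the oocyte / nurse-cell compartment.

A single order parameter psi (1 = oocyte, 0 = nurse compartment) evolves
inside a fixed elliptical medial-section domain whose boundary represents
the contact surface with the follicle epithelium.  The boundary carries a
signed, time-dependent effective-affinity field g(s, t) derived from
per-row Eya dynamics: g > 0 favours nurse-compartment contact with the
epithelium, g < 0 favours oocyte contact.  The interface angle at the
oocyte / nurse / epithelium triple points reads out the local affinity
balance (90 deg = balanced; < 90 deg = effective oocyte affinity).

Energetics (grid units)::

    E[psi] = int_domain  kappa/2 |grad psi|^2 + g_w psi^2 (1-psi)^2  dA
           - s_growth * (A - A^2 / (2 A_sat))
           + int_boundary g(s, t) h(psi)                           ds

with the smoothed step h(psi) = psi^2 (3 - 2 psi) and the oocyte area
A = int h(psi) dA.  The interface tension is gamma = sqrt(2 kappa g_w)/6
and Young's law for this wetting term is cos(theta) = -g / gamma, theta
measured through the oocyte.  The saturating growth drive (supply-limited
oocyte growth relative to the nurse compartment, fading linearly towards
the saturation area A_sat) makes the oocyte size a *stable* equilibrium
between growth pressure, interface tension and boundary wetting; psi is
non-conserved, so the oocyte area fraction is an emergent output.

Relaxational (Allen-Cahn) dynamics are integrated with an explicit
masked finite-difference scheme; the missing-neighbour Laplacian encodes
zero-flux conditions on the staircase boundary and the wetting term is
applied on boundary pixels with arc-length-calibrated weights.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .affinity_schedules import (
    AffinityField,
    ScenarioSpec,
    T_END_H,
    boundary_affinity_field,
    scenario as make_scenario,
)

__all__ = [
    "GermlineParams",
    "GermlinePhaseFieldState",
    "GermlineTrajectory",
    "GermlineReadout",
    "SolverError",
    "UniformAffinity",
    "interface_tension",
    "init_germline",
    "energy",
    "evolve_germline",
    "readout_germline",
]


class SolverError(RuntimeError):
    """Raised on numerical failure of the phase-field integration."""


class UniformAffinity:
    """Constant boundary affinity g(s, t) = g0, for calibration runs."""

    def __init__(self, g0: float):
        self.g0 = float(g0)

    def __call__(self, s, t):
        s = np.asarray(s, dtype=float)
        out = np.full_like(s, self.g0)
        return out if s.ndim else float(out)


def _h(p: np.ndarray) -> np.ndarray:
    return p * p * (3.0 - 2.0 * p)


def _dh(p: np.ndarray) -> np.ndarray:
    return 6.0 * p * (1.0 - p)


@dataclass(frozen=True)
class GermlineParams:
    """Numerical and physical parameters of the germline model.

    Lengths are in grid units (one medial-section pixel); the simulation
    clock maps one developmental hour to ``tau_per_hour`` relaxation units.
    """

    nx: int = 180
    ny: int = 110
    semi_a: float = 84.0  # AP semi-axis
    semi_b: float = 50.0  # DV semi-axis
    kappa: float = 1.0  # gradient-energy coefficient
    g_w: float = 0.5  # double-well height
    mobility: float = 1.0
    growth_tilt: float = 0.011  # max bulk drive favouring the oocyte phase
    growth_sat_fraction: float = 0.40  # saturation area as domain fraction
    tau_per_hour: float = 120.0
    dt: float = 0.18
    eps_clip: float = 0.02

    @property
    def interface_width(self) -> float:
        return float(np.sqrt(2.0 * self.kappa / self.g_w))


def interface_tension(params: GermlineParams) -> float:
    """Interface tension gamma of the double-well profile."""
    return float(np.sqrt(2.0 * params.kappa * params.g_w) / 6.0)


# ----------------------------------------------------------------------------
# Domain construction
# ----------------------------------------------------------------------------


def _ellipse_geometry(params: GermlineParams) -> dict:
    """Mask, boundary bookkeeping and arc-length coordinates for the domain.

    The returned dict contains the domain mask, boundary-pixel indices with
    arc-length coordinates s in [0, 1] (anterior pole -> posterior pole,
    symmetric in the two halves), quadrature weights normalised to the true
    ellipse perimeter, posterior-pointing wall tangents, and an approximate
    distance-to-boundary map used by the angle readout.
    """
    nx, ny = params.nx, params.ny
    a, b = params.semi_a, params.semi_b
    cx, cy = (nx - 1) / 2.0, (ny - 1) / 2.0
    X, Y = np.meshgrid(np.arange(nx), np.arange(ny))  # shape (ny, nx)
    r = np.sqrt(((X - cx) / a) ** 2 + ((Y - cy) / b) ** 2)
    mask = r <= 1.0

    inner = (
        np.roll(mask, 1, 0)
        & np.roll(mask, -1, 0)
        & np.roll(mask, 1, 1)
        & np.roll(mask, -1, 1)
    )
    boundary = mask & ~inner
    by, bx = np.nonzero(boundary)

    nmiss = np.zeros_like(by, dtype=float)
    for dy, dx in ((1, 0), (-1, 0), (0, 1), (0, -1)):
        yy = np.clip(by + dy, 0, ny - 1)
        xx = np.clip(bx + dx, 0, nx - 1)
        nmiss += (~mask[yy, xx]).astype(float)
    nmiss = np.maximum(nmiss, 1.0)

    # parametric angle (0 = posterior pole, +/-pi = anterior pole)
    eta = np.arctan2((by - cy) / b, (bx - cx) / a)
    eta_dense = np.linspace(0.0, np.pi, 4001)
    darc = np.sqrt((a * np.sin(eta_dense)) ** 2 + (b * np.cos(eta_dense)) ** 2)
    cum = np.concatenate(
        [[0.0], np.cumsum((darc[1:] + darc[:-1]) / 2.0 * np.diff(eta_dense))]
    )
    half_perimeter = float(cum[-1])
    arc_from_post = np.interp(np.abs(eta), eta_dense, cum)
    s_coord = 1.0 - arc_from_post / half_perimeter

    perimeter = 2.0 * half_perimeter
    weights = nmiss * (perimeter / nmiss.sum())

    tx = a * np.sin(np.abs(eta))
    ty = -b * np.cos(eta) * np.sign(eta + 1e-12)
    norm = np.hypot(tx, ty)
    tangent_post = np.stack([tx / norm, ty / norm], axis=1)

    # approximate Euclidean distance to the ellipse boundary (valid near it)
    grad_r = np.sqrt(
        ((X - cx) / a**2) ** 2 + ((Y - cy) / b**2) ** 2
    ) / np.maximum(r, 1e-9)
    dist = (1.0 - r) / np.maximum(grad_r, 1e-9)

    return {
        "mask": mask,
        "by": by,
        "bx": bx,
        "s": s_coord,
        "weights": weights,
        "tangent_post": tangent_post,
        "perimeter": perimeter,
        "area": float(mask.sum()),
        "center": (cx, cy),
        "dist": dist,
    }


@dataclass
class GermlinePhaseFieldState:
    """Order parameter and domain bookkeeping at one instant."""

    psi: np.ndarray  # (ny, nx), 1 = oocyte
    boundary_affinity: AffinityField
    params: GermlineParams
    time_h: float = 0.0
    geom: dict = field(default_factory=dict, repr=False)

    def oocyte_area_fraction(self) -> float:
        m = self.geom["mask"]
        return float(_h(np.clip(self.psi[m], 0, 1)).sum() / m.sum())


@dataclass
class GermlineTrajectory:
    times_h: np.ndarray
    snapshots: list[np.ndarray]
    state: GermlinePhaseFieldState  # final state (carries geometry/params)
    scenario_name: str = ""


@dataclass
class GermlineReadout:
    """Time series of the morphological parameters of the simulation."""

    interface_angle: pd.DataFrame  # columns t_h, angle_deg (NaN = undefined)
    oocyte_interface_fraction: pd.DataFrame
    oocyte_area_fraction: pd.DataFrame

    def as_frame(self) -> pd.DataFrame:
        return self.interface_angle.merge(
            self.oocyte_interface_fraction, on="t_h"
        ).merge(self.oocyte_area_fraction, on="t_h")


# ----------------------------------------------------------------------------
# Initialisation
# ----------------------------------------------------------------------------


def init_germline(
    oocyte_fraction0: float = 1.0 / 16.0,
    seed: int = 0,
    params: GermlineParams | None = None,
    boundary_affinity: AffinityField | None = None,
) -> GermlinePhaseFieldState:
    """Posterior oocyte region of the given area fraction, smoothed interface.

    The oocyte starts as the posterior region beyond a straight DV chord
    whose enclosed area fraction equals ``oocyte_fraction0`` (the 1/16
    germline share of the freshly specified oocyte by default).  ``seed``
    fixes a tiny symmetry-breaking perturbation; identical seeds give
    identical fields.
    """
    if not 0.0 < oocyte_fraction0 < 1.0:
        raise ValueError("oocyte_fraction0 must lie in (0, 1)")
    params = params or GermlineParams()
    geom = _ellipse_geometry(params)
    mask = geom["mask"]
    X = np.arange(params.nx)[None, :] * np.ones((params.ny, 1))

    xs = np.sort(X[mask])
    x_chord = float(np.quantile(xs, 1.0 - oocyte_fraction0))

    psi = 0.5 * (1.0 + np.tanh((X - x_chord) / params.interface_width))
    rng = np.random.default_rng(seed)
    psi = np.clip(psi + 1e-6 * rng.standard_normal(psi.shape), 0.0, 1.0)
    psi[~mask] = 0.0

    if boundary_affinity is None:
        boundary_affinity = boundary_affinity_field(
            make_scenario("germline_wt").schedules
        )
    return GermlinePhaseFieldState(
        psi=psi,
        boundary_affinity=boundary_affinity,
        params=params,
        time_h=0.0,
        geom=geom,
    )


# ----------------------------------------------------------------------------
# Energy and dynamics
# ----------------------------------------------------------------------------


def _masked_laplacian(psi: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Five-point Laplacian with zero-flux conditions at the mask boundary."""
    out = np.zeros_like(psi)
    for axis, shift in ((0, 1), (0, -1), (1, 1), (1, -1)):
        nb = np.roll(psi, shift, axis=axis)
        nb_mask = np.roll(mask, shift, axis=axis)
        out += np.where(nb_mask, nb - psi, 0.0)
    out[~mask] = 0.0
    return out


def energy(state: GermlinePhaseFieldState, t_h: float | None = None) -> dict:
    """Energy terms of the state under the boundary affinities at ``t_h``."""
    p = state.params
    psi, mask = state.psi, state.geom["mask"]
    t_h = state.time_h if t_h is None else t_h

    gx = np.diff(psi, axis=1)
    gy = np.diff(psi, axis=0)
    edge_x = mask[:, :-1] & mask[:, 1:]
    edge_y = mask[:-1, :] & mask[1:, :]
    grad_term = 0.5 * p.kappa * (
        np.sum(gx[edge_x] ** 2) + np.sum(gy[edge_y] ** 2)
    )
    pm = np.clip(psi[mask], 0.0, 1.0)
    well = p.g_w * np.sum((pm * (1 - pm)) ** 2)
    A = float(np.sum(_h(pm)))
    A_sat = p.growth_sat_fraction * state.geom["area"]
    tilt = -p.growth_tilt * (A - A * A / (2.0 * A_sat))

    by, bx = state.geom["by"], state.geom["bx"]
    g_vals = state.boundary_affinity(state.geom["s"], t_h)
    wet = float(
        np.sum(g_vals * state.geom["weights"] * _h(np.clip(psi[by, bx], 0, 1)))
    )

    terms = {
        "interfacial": float(grad_term + well),
        "growth_tilt": float(tilt),
        "wetting": wet,
    }
    terms["total"] = float(sum(terms.values()))
    return terms


def evolve_germline(
    state: GermlinePhaseFieldState,
    scenario: ScenarioSpec | str | None = None,
    t_end: float = T_END_H,
    dt: float | None = None,
    sample_every_h: float = 0.5,
    energy_check_every: int = 0,
) -> GermlineTrajectory:
    """Relaxational evolution of psi under the scenario's affinity schedule.

    ``scenario`` may be a germline ScenarioSpec, a scenario name, or None to
    keep the affinity field already attached to the state.  With
    ``energy_check_every`` > 0 the solver verifies at that step interval
    that a step at frozen affinities does not increase the energy and
    raises :class:`SolverError` otherwise.
    """
    p = state.params
    dt = p.dt if dt is None else dt
    if dt <= 0 or dt * p.mobility * p.kappa > 0.25:
        raise SolverError(
            f"dt={dt} unstable for explicit diffusion with kappa={p.kappa}"
        )

    name = ""
    if scenario is not None:
        if isinstance(scenario, str):
            scenario = make_scenario(scenario)
        if scenario.model != "germline":
            raise ValueError("scenario is not a germline-model scenario")
        name = scenario.name
        state = replace(
            state, boundary_affinity=boundary_affinity_field(scenario.schedules)
        )

    mask = state.geom["mask"]
    by, bx = state.geom["by"], state.geom["bx"]
    s = state.geom["s"]
    weights = state.geom["weights"]
    area_dom = state.geom["area"]
    aff = state.boundary_affinity

    psi = state.psi.copy()
    t_h = float(state.time_h)
    n_steps = int(np.ceil((t_end - t_h) * p.tau_per_hour / dt))
    sample_every = max(1, int(round(sample_every_h * p.tau_per_hour / dt)))

    times = [t_h]
    snaps = [psi.copy()]

    for step in range(1, n_steps + 1):
        g_vals = aff(s, t_h)

        if energy_check_every and step % energy_check_every == 0:
            probe = replace(state, psi=psi, time_h=t_h)
            e_before = energy(probe, t_h)["total"]

        lap = _masked_laplacian(psi, mask)
        dpsi = p.kappa * lap - 2.0 * p.g_w * psi * (1 - psi) * (1 - 2 * psi)
        A = float(np.sum(_h(psi[mask])))
        drive = p.growth_tilt * (1.0 - A / (p.growth_sat_fraction * area_dom))
        dpsi += drive * _dh(psi)
        dpsi[by, bx] -= g_vals * weights * _dh(psi[by, bx])
        psi = psi + dt * p.mobility * dpsi
        np.clip(psi, 0.0, 1.0, out=psi)
        psi[~mask] = 0.0

        if energy_check_every and step % energy_check_every == 0:
            probe = replace(state, psi=psi, time_h=t_h)
            e_after = energy(probe, t_h)["total"]
            if e_after > e_before + 1e-6 * abs(e_before) + 1e-8:
                raise SolverError(
                    f"energy increased at step {step}: {e_before} -> {e_after}"
                )

        t_h += dt / p.tau_per_hour
        if step % sample_every == 0 or step == n_steps:
            times.append(t_h)
            snaps.append(psi.copy())

    final = replace(state, psi=psi, time_h=t_h)
    return GermlineTrajectory(
        times_h=np.asarray(times), snapshots=snaps, state=final, scenario_name=name
    )


# ----------------------------------------------------------------------------
# Readouts
# ----------------------------------------------------------------------------


def triple_point_angle(
    psi: np.ndarray, geom: dict, band: tuple[float, float] = (1.5, 4.5)
) -> float:
    """Contact angle (deg) at the psi = 0.5 triple points, through the oocyte.

    At each of the two (upper / lower) boundary contacts the interface
    direction is the level-set tangent of psi oriented into the domain; the
    reported angle is measured against the posterior-pointing wall tangent,
    so oocyte wetting (interface leaning over the oocyte) gives < 90 deg.
    Returns NaN when the interface does not reach the boundary.
    """
    cx, cy = geom["center"]
    dist = geom["dist"]
    mask = geom["mask"]
    by, bx = geom["by"], geom["bx"]

    Y = np.arange(psi.shape[0])[:, None] * np.ones((1, psi.shape[1]))
    gy_f, gx_f = np.gradient(psi)

    angles = []
    for half in (1, -1):
        sel = mask & (dist > band[0]) & (dist < band[1]) & ((Y - cy) * half > 0)
        ys, xs_ = np.nonzero(sel)
        if ys.size == 0:
            continue
        vals = psi[ys, xs_]
        near = np.abs(vals - 0.5) < 0.2
        if not np.any(near):
            continue
        half_angles = []
        for y0, x0 in zip(ys[near], xs_[near]):
            gx = gx_f[max(y0 - 1, 0) : y0 + 2, max(x0 - 1, 0) : x0 + 2].mean()
            gy = gy_f[max(y0 - 1, 0) : y0 + 2, max(x0 - 1, 0) : x0 + 2].mean()
            gnorm = np.hypot(gx, gy)
            if gnorm < 1e-8:
                continue
            nvec = np.array([gx, gy]) / gnorm  # points toward the oocyte
            dvec = np.array([-nvec[1], nvec[0]])
            to_center = np.array([cx - x0, cy - y0])
            if dvec @ to_center < 0:
                dvec = -dvec
            j = int(np.argmin((bx - x0) ** 2 + (by - y0) ** 2))
            wpost = geom["tangent_post"][j]
            cosang = float(np.clip(dvec @ wpost, -1.0, 1.0))
            half_angles.append(np.degrees(np.arccos(cosang)))
        if half_angles:
            angles.append(float(np.median(half_angles)))
    if not angles:
        return float("nan")
    return float(np.mean(angles))


def readout_germline(traj: GermlineTrajectory) -> GermlineReadout:
    """Interface angle and oocyte fractions over the trajectory."""
    if not traj.snapshots:
        raise ValueError("empty trajectory")
    geom = traj.state.geom
    by, bx = geom["by"], geom["bx"]
    weights = geom["weights"]
    mask = geom["mask"]

    rows_angle, rows_if, rows_area = [], [], []
    for t_h, psi in zip(traj.times_h, traj.snapshots):
        ang = triple_point_angle(psi, geom)
        frac_if = float(
            np.sum(weights * _h(np.clip(psi[by, bx], 0, 1))) / weights.sum()
        )
        frac_area = float(_h(np.clip(psi[mask], 0, 1)).sum() / mask.sum())
        rows_angle.append({"t_h": t_h, "angle_deg": ang})
        rows_if.append({"t_h": t_h, "oocyte_interface_fraction": frac_if})
        rows_area.append({"t_h": t_h, "oocyte_area_fraction": frac_area})
    return GermlineReadout(
        interface_angle=pd.DataFrame(rows_angle),
        oocyte_interface_fraction=pd.DataFrame(rows_if),
        oocyte_area_fraction=pd.DataFrame(rows_area),
    )
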