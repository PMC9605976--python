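"""Multicellular phase-field model of follicle cells on the germline surface.

N follicle cells (FCs) are smooth indicator fields phi_i in [0, 1] on a
2-D strip whose bottom boundary is the germline surface, split into an
*affine* (nurse-cell) anterior compartment and a *non-affine* (oocyte)
posterior compartment.  Affinity is the energetic preference of a cell for
contact with the affine compartment; per-cell affinities a_i(t) follow the
Eya row schedules (rows 1-6 = anterior FC rows, the row-7 dynamic is
shared by cells 7-14).

Energy (grid units)::

    E = sum_i  int  kappa/2 |grad phi_i|^2 + g_w phi_i^2 (1 - phi_i)^2  dA
             + lambda_v (V_i - V_i^0)^2
             + beta sum_{i<j} int phi_i^2 phi_j^2 dA
             - int_bottom (w_0 + a_i(t) chi_affine(x)) h(phi_i) dx

with h(phi) = phi^2 (3 - 2 phi) and cell volume V_i = int h(phi_i) dA.
Volumes are held constant (the model contains no germline growth) by a
Lagrange-like projection: each step a fraction of the volume defect is
corrected along the interface indicator h'(phi), which is unconditionally
stable (a direct penalty force has a per-step feedback gain well above 1
on these grids and limit-cycles).  The quadratic volume term is retained
in the reported energy.  w_0 is a small uniform attachment of the
epithelium to the whole germline surface on top of which the
Eya-dependent reward acts.

Two lateral boundary conditions are supported: the 14-cell egg-chamber
model uses *mirror* (Neumann) ends — the domain is one side of a medial
section, the end cells span the anterior / posterior poles and are
represented as half cells at the symmetry axes — while small-n cell-patch
models (e.g. the 3-cell clone experiments) use a *periodic* ring, making
all cells equivalent.  Relaxational dynamics are integrated with an
explicit single-precision finite-difference scheme.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .affinity_schedules import (
    ScenarioSpec,
    T_END_H,
    scenario as make_scenario,
)

__all__ = [
    "FCParams",
    "FCPhaseFieldState",
    "FCTrajectory",
    "FCReadout",
    "SolverError",
    "init_fc",
    "energy",
    "evolve_fc",
    "readout_fc",
]


class SolverError(RuntimeError):
    """Raised on numerical failure of the phase-field integration."""


def _h(p: np.ndarray) -> np.ndarray:
    return p * p * (3.0 - 2.0 * p)


def _dh(p: np.ndarray) -> np.ndarray:
    return 6.0 * p * (1.0 - p)


@dataclass(frozen=True)
class FCParams:
    """Numerical and physical parameters of the follicle-cell model.

    Lengths are grid units; one developmental hour maps to
    ``tau_per_hour`` relaxation units.  The affinity scale ``kappa_fc``
    (contact-energy reward per Eya arb. unit) and baseline attachment
    ``w0`` are the wild-type calibration; all perturbation scenarios reuse
    them unchanged.
    """

    nx: int = 256
    ny: int = 64
    kappa: float = 1.0  # gradient-energy coefficient
    g_w: float = 0.25  # double-well height
    lambda_v: float = 0.06  # volume-energy stiffness (reporting)
    vproj_rate: float = 0.5  # fraction of the volume defect corrected per step
    vproj_cap: float = 0.04  # cap on the per-step volume-correction amplitude
    beta: float = 2.5  # pairwise overlap penalty
    w0: float = 0.55  # uniform boundary attachment
    kappa_fc: float = 0.012  # Eya -> affinity scale
    mobility: float = 1.0
    affine_fraction: float = 0.575  # nurse-cell share of the bottom boundary
    init_height: float = 18.0
    tau_per_hour: float = 75.0
    dt: float = 0.2
    eps_clip: float = 0.02
    detach_rel: float = 0.01  # contact below this fraction of perimeter = off
    boundary: str = "auto"  # 'mirror' | 'periodic' | 'auto'

    @property
    def interface_width(self) -> float:
        return float(np.sqrt(2.0 * self.kappa / self.g_w))


@dataclass
class FCPhaseFieldState:
    """N indicator fields and bookkeeping at one instant."""

    phi: np.ndarray  # (n_cells, ny, nx), float32
    target_volumes: np.ndarray  # (n_cells,)
    affine_mask: np.ndarray  # (nx,) bool
    params: FCParams
    boundary: str = "mirror"
    time_h: float = 0.0
    seed: int = 0

    @property
    def n_cells(self) -> int:
        return self.phi.shape[0]

    def volumes(self) -> np.ndarray:
        return _h(np.clip(self.phi, 0, 1)).sum(axis=(1, 2), dtype=np.float64)

    def contact_lengths(self) -> tuple[np.ndarray, np.ndarray]:
        """Per-cell contact length on the (affine, non-affine) segments."""
        bottom = _h(np.clip(self.phi[:, 0, :], 0, 1))
        aff = bottom[:, self.affine_mask].sum(axis=1, dtype=np.float64)
        non = bottom[:, ~self.affine_mask].sum(axis=1, dtype=np.float64)
        return aff, non


@dataclass
class FCTrajectory:
    times_h: np.ndarray
    contact_affine: np.ndarray  # (n_samples, n_cells)
    contact_nonaffine: np.ndarray
    volumes: np.ndarray
    state: FCPhaseFieldState  # final state
    scenario_name: str = ""
    snapshots: list = field(default_factory=list)


@dataclass
class FCReadout:
    """Contact-length time series, apical extents and the detached set."""

    contact_lengths: pd.DataFrame  # cell, t_h, affine, non_affine, total
    apical_extent_sq: pd.DataFrame  # cell, t_h, extent_sq
    detached: set[int] = field(default_factory=set)
    on_affine_final: tuple[int, ...] = ()
    on_nonaffine_final: tuple[int, ...] = ()


# ----------------------------------------------------------------------------
# Initialisation
# ----------------------------------------------------------------------------


def init_fc(
    n_cells: int = 14,
    domain: tuple[int, int] | None = None,
    affine_fraction: float | None = None,
    seed: int = 0,
    params: FCParams | None = None,
) -> FCPhaseFieldState:
    """Equal-volume cells seeded side by side on the bottom boundary.

    Cells are ordered anterior (cell 1, x = 0) to posterior.  With mirror
    ends (the default for the 14-cell chamber) the first and last cells
    are half cells spanning the pole symmetry axes; with a periodic ring
    all cells are congruent.  Initialisation is deterministic; ``seed`` is
    recorded for reproducibility bookkeeping.
    """
    params = params or FCParams()
    if domain is not None:
        params = replace(params, nx=domain[0], ny=domain[1])
    if affine_fraction is not None:
        params = replace(params, affine_fraction=affine_fraction)
    if not 0.0 < params.affine_fraction <= 1.0:
        raise ValueError("affine_fraction must lie in (0, 1]")
    boundary = params.boundary
    if boundary == "auto":
        boundary = "mirror" if n_cells >= 8 else "periodic"
    nx, ny = params.nx, params.ny
    if n_cells < 1 or nx / n_cells < 4 * params.interface_width:
        raise ValueError(
            f"domain of width {nx} too small for {n_cells} cells at "
            f"interface width {params.interface_width:.1f}"
        )

    w = params.interface_width / 2.0
    x = np.arange(nx, dtype=np.float32)
    y = np.arange(ny, dtype=np.float32)
    X, Y = np.meshgrid(x, y)

    def sig(z):
        return 0.5 * (1.0 + np.tanh(z / w))

    cap = sig(params.init_height - Y)
    phi = np.empty((n_cells, ny, nx), dtype=np.float32)
    if boundary == "mirror":
        wc = nx / (n_cells - 1.0)
        bounds = np.concatenate(
            [[0.0], [wc / 2 + i * wc for i in range(n_cells - 1)], [float(nx)]]
        )
        for i in range(n_cells):
            phi[i] = sig(X - bounds[i]) * sig(bounds[i + 1] - X) * cap
        phi[0] = sig(bounds[1] - X) * cap  # half cell across the anterior pole
        phi[-1] = sig(X - bounds[-2]) * cap  # half cell across the posterior pole
    else:
        wc = nx / float(n_cells)
        for i in range(n_cells):
            centre = (i + 0.5) * wc
            xi = (X - centre + nx / 2.0) % nx - nx / 2.0  # wrapped coordinate
            phi[i] = sig(xi + wc / 2.0) * sig(wc / 2.0 - xi) * cap
    phi = np.clip(phi, 0.0, 1.0).astype(np.float32)

    affine_mask = x < params.affine_fraction * nx
    return FCPhaseFieldState(
        phi=phi,
        target_volumes=_h(phi).sum(axis=(1, 2), dtype=np.float64),
        affine_mask=affine_mask,
        params=params,
        boundary=boundary,
        seed=seed,
    )


# ----------------------------------------------------------------------------
# Energy and dynamics
# ----------------------------------------------------------------------------


def _affinities(n: int, scenario: ScenarioSpec, t_h: float, kappa_fc: float) -> np.ndarray:
    E = np.asarray([scenario.schedules[i + 1](t_h) for i in range(n)], dtype=float)
    return kappa_fc * E


def energy(
    state: FCPhaseFieldState, affinities: np.ndarray | None = None
) -> dict[str, float]:
    """Energy terms for the given per-cell affinities (default: zero)."""
    p = state.params
    phi = np.asarray(state.phi, dtype=np.float64)
    n = state.n_cells
    a = np.zeros(n) if affinities is None else np.asarray(affinities, dtype=float)

    gx = np.diff(phi, axis=2)
    gy = np.diff(phi, axis=1)
    grad = 0.5 * p.kappa * (np.sum(gx**2) + np.sum(gy**2))
    if state.boundary == "periodic":
        grad += 0.5 * p.kappa * np.sum((phi[:, :, 0] - phi[:, :, -1]) ** 2)
    pc = np.clip(phi, 0.0, 1.0)
    well = p.g_w * np.sum((pc * (1 - pc)) ** 2)

    V = _h(pc).sum(axis=(1, 2))
    vol = p.lambda_v * np.sum((V - state.target_volumes) ** 2)

    sq = pc**2
    S = sq.sum(axis=0)
    overlap = 0.5 * p.beta * np.sum(sq * (S - sq))

    bottom = _h(pc[:, 0, :])
    chi = state.affine_mask.astype(float)
    contact = -np.sum((p.w0 + a[:, None] * chi[None, :]) * bottom)

    terms = {
        "interfacial": float(grad + well),
        "volume": float(vol),
        "overlap": float(overlap),
        "contact": float(contact),
    }
    terms["total"] = float(sum(terms.values()))
    return terms


def _laplacian(pc: np.ndarray, periodic_x: bool) -> np.ndarray:
    lap = (
        np.roll(pc, 1, 1)
        + np.roll(pc, -1, 1)
        + np.roll(pc, 1, 2)
        + np.roll(pc, -1, 2)
        - 4.0 * pc
    )
    # Neumann in y always (top free surface, bottom germline wall)
    lap[:, 0, :] += pc[:, 0, :] - pc[:, -1, :]
    lap[:, -1, :] += pc[:, -1, :] - pc[:, 0, :]
    if not periodic_x:
        lap[:, :, 0] += pc[:, :, 0] - pc[:, :, -1]
        lap[:, :, -1] += pc[:, :, -1] - pc[:, :, 0]
    return lap


def evolve_fc(
    state: FCPhaseFieldState,
    scenario: ScenarioSpec | str = "wt",
    t_end: float = T_END_H,
    dt: float | None = None,
    sample_every_h: float = 0.5,
    energy_check_every: int = 0,
    store_snapshots: bool = False,
) -> FCTrajectory:
    """Explicit gradient flow with time-varying affinities a_i(t).

    Raises :class:`SolverError` on an unstable step size, on non-finite
    fields, or — when ``energy_check_every`` > 0 — if a step at frozen
    affinities increases the energy.
    """
    p = state.params
    dt = p.dt if dt is None else dt
    if dt <= 0 or dt * p.mobility * p.kappa > 0.25:
        raise SolverError(
            f"dt={dt} unstable for explicit diffusion with kappa={p.kappa}"
        )
    if isinstance(scenario, str):
        scenario = make_scenario(scenario)
    if scenario.model != "fc":
        raise ValueError("scenario is not an FC-model scenario")
    missing = [i + 1 for i in range(state.n_cells) if i + 1 not in scenario.schedules]
    if missing:
        raise ValueError(f"scenario lacks schedules for cells {missing}")

    periodic_x = state.boundary == "periodic"
    n = state.n_cells
    chi = state.affine_mask.astype(np.float32)
    V0 = state.target_volumes
    phi = np.asarray(state.phi, dtype=np.float32).copy()
    t_h = float(state.time_h)
    n_steps = int(np.ceil((t_end - t_h) * p.tau_per_hour / dt))
    sample_every = max(1, int(round(sample_every_h * p.tau_per_hour / dt)))
    refresh_every = max(1, int(round(0.05 * p.tau_per_hour / dt)))

    kk = np.float32(p.kappa)
    gw2 = np.float32(2.0 * p.g_w)
    b2 = np.float32(2.0 * p.beta)
    mdt = np.float32(p.mobility * dt)

    def sample(ph, t):
        b = _h(np.clip(ph[:, 0, :], 0, 1)).astype(np.float64)
        return (
            t,
            b[:, state.affine_mask].sum(axis=1),
            b[:, ~state.affine_mask].sum(axis=1),
            _h(np.clip(ph, 0, 1)).sum(axis=(1, 2), dtype=np.float64),
        )

    samples = [sample(phi, t_h)]
    snaps = [(t_h, phi.copy())] if store_snapshots else []
    wet = None

    for step in range(n_steps):
        if step % refresh_every == 0:
            a = _affinities(n, scenario, t_h, p.kappa_fc).astype(np.float32)
            wet = (np.float32(p.w0) + a[:, None] * chi[None, :]).astype(np.float32)

        if energy_check_every and step and step % energy_check_every == 0:
            e_before = energy(replace(state, phi=phi), a)["total"]

        pc = np.clip(phi, 0, 1)
        lap = _laplacian(pc, periodic_x)
        sq = pc * pc
        S = sq.sum(axis=0)
        V = _h(pc).sum(axis=(1, 2))
        dh = 6.0 * pc * (1 - pc)
        react = kk * lap - gw2 * pc * (1 - pc) * (1 - 2 * pc)
        react -= b2 * pc * (S[None] - sq)
        react[:, 0, :] += wet * dh[:, 0, :]
        phi += mdt * react
        # Lagrange-like volume projection along the interface indicator
        denom = (dh * dh).sum(axis=(1, 2))
        c = np.clip(
            p.vproj_rate * (V0 - V) / np.maximum(denom, 1e-6),
            -p.vproj_cap,
            p.vproj_cap,
        ).astype(np.float32)
        phi += c[:, None, None] * dh
        np.clip(phi, -p.eps_clip, 1.0 + p.eps_clip, out=phi)

        if energy_check_every and step and step % energy_check_every == 0:
            if not np.all(np.isfinite(phi)):
                raise SolverError(f"non-finite fields at step {step}")
            e_after = energy(replace(state, phi=phi), a)["total"]
            if e_after > e_before + 1e-5 * abs(e_before) + 1e-6:
                raise SolverError(
                    f"energy increased at step {step}: {e_before} -> {e_after}"
                )

        t_h += dt / p.tau_per_hour
        if (step + 1) % sample_every == 0 or step == n_steps - 1:
            samples.append(sample(phi, t_h))
            if store_snapshots:
                snaps.append((t_h, phi.copy()))

    if not np.all(np.isfinite(phi)):
        raise SolverError("non-finite fields at the end of the run")
    final = replace(state, phi=phi, time_h=t_h)
    return FCTrajectory(
        times_h=np.asarray([s[0] for s in samples]),
        contact_affine=np.asarray([s[1] for s in samples]),
        contact_nonaffine=np.asarray([s[2] for s in samples]),
        volumes=np.asarray([s[3] for s in samples]),
        state=final,
        scenario_name=scenario.name,
        snapshots=snaps,
    )


# ----------------------------------------------------------------------------
# Readout
# ----------------------------------------------------------------------------


def readout_fc(traj: FCTrajectory) -> FCReadout:
    """Contact-length tables, (apical length)^2 and compartment assignment.

    A cell is *detached* when its total boundary contact stays below
    ``detach_rel`` of its perimeter estimate (4 sqrt(V)) over the final 10%
    of the run; the same threshold classifies cells as on / off each
    boundary compartment at final time.
    """
    if traj.times_h.size == 0:
        raise ValueError("empty trajectory")
    p = traj.state.params
    n = traj.state.n_cells
    V0 = traj.state.target_volumes
    thresh = p.detach_rel * 4.0 * np.sqrt(V0)

    rows = []
    for k, t in enumerate(traj.times_h):
        for i in range(n):
            rows.append(
                {
                    "cell": i + 1,
                    "t_h": t,
                    "affine": traj.contact_affine[k, i],
                    "non_affine": traj.contact_nonaffine[k, i],
                    "total": traj.contact_affine[k, i]
                    + traj.contact_nonaffine[k, i],
                }
            )
    contact = pd.DataFrame(rows)
    apical = contact.assign(extent_sq=lambda d: d["total"] ** 2)[
        ["cell", "t_h", "extent_sq"]
    ]

    t0, t1 = traj.times_h[0], traj.times_h[-1]
    tail = traj.times_h >= t0 + 0.9 * (t1 - t0)
    total_tail = (traj.contact_affine + traj.contact_nonaffine)[tail]
    detached = {i + 1 for i in range(n) if np.all(total_tail[:, i] < thresh[i])}
    aff_f = traj.contact_affine[-1]
    non_f = traj.contact_nonaffine[-1]
    return FCReadout(
        contact_lengths=contact,
        apical_extent_sq=apical,
        detached=detached,
        on_affine_final=tuple(i + 1 for i in range(n) if aff_f[i] >= thresh[i]),
        on_nonaffine_final=tuple(i + 1 for i in range(n) if non_f[i] >= thresh[i]),
    )
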