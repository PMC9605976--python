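"""Seeded synthetic egg chambers with the statistical structure of the assay.

The generator replaces the confocal dataset: it produces 2-D medial-section
egg-chamber geometries (elliptical outline, posterior oocyte compartment,
perimeter follicle cells with fates and Eya intensities, sectioned nurse
cells) whose morphometric structure follows the wild-type progression --
germline area as the continuous developmental coordinate, an oocyte growing
from 1/16 of the germline to a ~40% plateau near the end of phase 2,
anterior-FC flattening in phases 2-3, and per-row Eya dynamics taken from
the shared schedule module.  Genotype switches modify Eya / fate / shape
rules only beyond the relevant critical germline size.

All randomness is multiplicative log-normal (Eya) or additive Gaussian
(contour coordinates) measurement noise plus a biological nurse-cell
heterogeneity; a single root seed is split into independent per-chamber
streams via ``numpy.random.SeedSequence``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .affinity_schedules import (
    EYA_ZERO_AFFINITY,
    PHASE_T12_H,
    PHASE_T23_H,
    T_END_H,
    _smoothstep,
    default_row_positions,
    default_schedules,
)

__all__ = [
    "GermlineCyst",
    "EggChamberGeometry",
    "GeneratorConfig",
    "GENOTYPES",
    "area_to_time",
    "oocyte_fraction_wt",
    "generate_cyst",
    "generate_chamber",
    "generate_cohort",
    "cohort_tables",
]

GENOTYPES = ("wt", "mirr_eya", "gr1_eyaRNAi", "tj_egfr", "custom")

#: Angle response of the interface angle to the Eya level of the follicle
#: cells overlying the nurse-cell--oocyte boundary (degrees per arb. unit);
#: the zero-affinity level of 72 arb. unit maps to the balanced 90-degree
#: angle.
ANGLE_PER_EYA = 0.3

#: Eya level of an Eya-negative epithelium (knockdown / EGFR-activated).
LOW_EYA = 20.0

#: Late-development oocyte share of the germline (wild type plateau).
OOCYTE_PLATEAU = 0.40


@dataclass(frozen=True)
class GermlineCyst:
    """A 16-cell germline cyst: 1 oocyte + 15 nurse cells."""

    roles: tuple[str, ...]
    volume_fractions: tuple[float, ...]

    def __post_init__(self):
        if len(self.roles) != 16 or len(self.volume_fractions) != 16:
            raise ValueError("a germline cyst has exactly 16 cells")
        if sum(r == "oocyte" for r in self.roles) != 1:
            raise ValueError("a germline cyst has exactly one oocyte")
        fr = np.asarray(self.volume_fractions)
        if np.any(fr <= 0):
            raise ValueError("volume fractions must be positive")
        if abs(fr.sum() - 1.0) > 1e-9:
            raise ValueError("volume fractions must sum to 1")

    @property
    def n_cells(self) -> int:
        return 16

    @property
    def nurse_fractions(self) -> np.ndarray:
        return np.asarray(
            [f for r, f in zip(self.roles, self.volume_fractions) if r == "nurse"]
        )


@dataclass
class EggChamberGeometry:
    """One egg chamber's 2-D medial-section geometry and per-cell fields.

    ``fc_positions`` are arc-length coordinates (µm) along the outer
    contour, measured from the anterior pole going through the upper half;
    ``nc_oocyte_interface`` is the sampled oocyte / nurse-compartment
    interface curve.  The oocyte occupies the posterior part of the section.
    """

    outer_contour: np.ndarray  # (m, 2) closed planar curve, µm
    aspect_ratio_AP: float
    germline_area: float  # µm^2
    oocyte_area: float  # µm^2
    nc_oocyte_interface: np.ndarray  # (k, 2) curve, µm
    triple_eta: float  # ellipse parameter of the upper triple point
    fc_positions: np.ndarray  # arc-length coords, µm, strictly increasing
    fc_extents: np.ndarray  # apical extent per section FC, µm
    fc_fate: np.ndarray  # 'AFC' | 'MBFC' | 'PFC'
    fc_eya: np.ndarray  # arb. unit
    fc_total_count_3d: int
    afc_count_3d: int
    interface_angle_true: float  # degrees
    nc_section_area_fractions: np.ndarray  # per visible nurse cell
    nc_section_interface_fractions: np.ndarray
    genotype: str = "wt"
    chamber_id: int = 0
    semi_axes: tuple[float, float] = (0.0, 0.0)
    time_h: float = 0.0

    def __post_init__(self):
        if self.germline_area <= 0:
            raise ValueError("germline area must be positive")
        if np.any(self.fc_eya < 0):
            raise ValueError("Eya intensities must be non-negative")
        if np.any(np.diff(self.fc_positions) <= 0):
            raise ValueError("fc positions must be strictly increasing")


@dataclass(frozen=True)
class GeneratorConfig:
    """Cohort-level generator settings (defaults = wild-type study design)."""

    seed: int = 0
    n_chambers: int = 126
    area_range: tuple[float, float] = (800.0, 45000.0)  # µm^2
    genotype: str = "wt"
    fc_count_at_arrest: int = 850
    afc_fraction: float = 0.10
    phase1_aspect_ratio: float = 1.5
    noise_cv: float = 0.05
    critical_size_mirr: float = 11650.0  # µm^2
    critical_size_gr1: float = 1600.0  # µm^2
    n_section_fcs: int = 60
    nurse_heterogeneity: float = 0.08  # biological CV of nurse-cell sizes

    def __post_init__(self):
        if not 0 < self.afc_fraction < 1:
            raise ValueError("afc_fraction must lie in (0, 1)")
        lo, hi = self.area_range
        if lo <= 0 or hi <= lo:
            raise ValueError("area_range must be positive and increasing")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be non-negative")
        if self.genotype not in GENOTYPES:
            raise ValueError(f"unknown genotype {self.genotype!r}")

    def to_json(self) -> str:
        d = {k: getattr(self, k) for k in self.__dataclass_fields__}
        return json.dumps(d, indent=2)


# ----------------------------------------------------------------------------
# Developmental progression rules
# ----------------------------------------------------------------------------

#: Exponential growth rate of germline area fitted through the two phase
#: boundaries (6500 µm^2 at mid stage 7, 31500 µm^2 at mid stage 10a).
_GROWTH_RATE = float(np.log(31500.0 / 6500.0) / (PHASE_T23_H - PHASE_T12_H))
_AREA_T0 = 6500.0 / np.exp(_GROWTH_RATE * PHASE_T12_H)


def area_to_time(area: float | np.ndarray) -> float | np.ndarray:
    """Map germline area (µm^2) to the 36-h developmental clock (clipped)."""
    t = np.log(np.asarray(area, dtype=float) / _AREA_T0) / _GROWTH_RATE
    t = np.clip(t, 0.0, T_END_H)
    return t if t.ndim else float(t)


def oocyte_fraction_wt(area: float) -> float:
    """Wild-type oocyte share of the germline section as a function of area.

    1/16 through phase 1, rising smoothly through phase 2 and plateauing at
    ~40% before the phase-2/3 boundary.
    """
    s = _smoothstep((area - 6500.0) / (27000.0 - 6500.0))
    return float(1.0 / 16.0 + (OOCYTE_PLATEAU - 1.0 / 16.0) * s)


def _aspect_ratio(area: float, phase1_aspect: float) -> float:
    s = np.clip((area - 6500.0) / (45000.0 - 6500.0), 0.0, 1.0)
    return float(phase1_aspect + (2.0 - phase1_aspect) * s)


def _flattening_progress(area: float) -> float:
    """0 before AFC flattening starts, 1 when the matched state is reached."""
    return float(_smoothstep((area - 6500.0) / (27000.0 - 6500.0)))


# ----------------------------------------------------------------------------
# Ellipse helpers
# ----------------------------------------------------------------------------


def _ellipse_axes(area: float, aspect: float) -> tuple[float, float]:
    b = np.sqrt(area / (np.pi * aspect))
    return aspect * b, b  # (semi-AP, semi-DV)


def _arc_table(a: float, b: float, n: int = 2048):
    """Cumulative arc length of the ellipse quarter eta in [0, pi]."""
    eta = np.linspace(0.0, np.pi, n)
    de = np.sqrt((a * np.sin(eta)) ** 2 + (b * np.cos(eta)) ** 2)
    cum = np.concatenate([[0.0], np.cumsum((de[1:] + de[:-1]) / 2 * np.diff(eta))])
    return eta, cum  # arc measured from the posterior pole (eta = 0)


def _segment_area(a: float, b: float, eta0: float) -> float:
    """Area of the posterior elliptical segment cut at parameter eta0."""
    # region {eta in (-eta0, eta0)} bounded by the chord x = a cos(eta0)
    return a * b * (eta0 - np.sin(eta0) * np.cos(eta0))


def _solve_posterior_cap(a: float, b: float, target_area: float) -> float:
    """Parameter eta0 of the chord enclosing the target posterior area."""
    return brentq(
        lambda e: _segment_area(a, b, e) - target_area, 1e-6, np.pi - 1e-6
    )


def _solve_interface(
    a: float, b: float, target_area: float, angle_deg: float, n: int = 201
) -> tuple[float, np.ndarray]:
    """Oocyte interface: straight DV chord with a local endpoint bend.

    The triple points stay on the chord of the posterior segment (so the
    oocyte contact arc is the segment arc), while the requested contact
    angle is encoded as a local tangent rotation at the endpoints decaying
    over a fraction of the half-chord.  The chord position is re-solved so
    the enclosed area matches ``target_area`` exactly despite the bend.
    """
    decay = 0.15  # bend decay length as a fraction of the half-chord

    def curve_for(eta0: float) -> np.ndarray:
        x0, y0 = a * np.cos(eta0), b * np.sin(eta0)
        delta = np.clip(angle_deg - _chord_contact_angle(a, b, eta0), -60.0, 60.0)
        w = decay * y0
        y = np.linspace(-y0, y0, n)
        # positive delta rotates the endpoint tangents anteriorly (away from
        # the posterior wall direction), widening the through-oocyte angle;
        # the bend is a local bump: zero at the triple points (which stay on
        # the ellipse), slope tan(delta) there, decaying toward mid-chord
        d = y0 - np.abs(y)
        bend = -np.tan(np.radians(delta)) * d * np.exp(-d / w)
        return np.stack([x0 + bend, y], axis=1)

    def area_of(eta0: float) -> float:
        x0, y0 = a * np.cos(eta0), b * np.sin(eta0)
        c = curve_for(eta0)
        bend_area = float(np.trapezoid(c[:, 0] - x0, c[:, 1]))
        return _segment_area(a, b, eta0) - bend_area

    eta0 = brentq(
        lambda e: area_of(e) - target_area, 1e-3, np.pi - 1e-3, xtol=1e-10
    )
    return eta0, curve_for(eta0)


def _chord_contact_angle(a: float, b: float, eta0: float) -> float:
    """Angle (deg, through the oocyte) between a DV chord and the ellipse."""
    # ellipse tangent at (a cos, b sin), pointing toward the posterior pole
    tx, ty = a * np.sin(eta0), -b * np.cos(eta0)
    # chord direction at the upper triple point, pointing into the domain
    dx, dy = 0.0, -1.0
    cosang = (tx * dx + ty * dy) / np.hypot(tx, ty)
    return float(np.degrees(np.arccos(np.clip(cosang, -1, 1))))


# ----------------------------------------------------------------------------
# Operations
# ----------------------------------------------------------------------------


def generate_cyst(seed: int, cv_volume: float) -> GermlineCyst:
    """A 16-cell cyst: oocyte at 1/16, nurse fractions noisy around equality."""
    if cv_volume < 0:
        raise ValueError("cv_volume must be non-negative")
    rng = np.random.default_rng(seed)
    nurse = np.ones(15)
    if cv_volume > 0:
        nurse *= np.exp(rng.normal(0.0, cv_volume, 15))
    nurse = nurse / nurse.sum() * (15.0 / 16.0)
    fractions = np.concatenate([[1.0 / 16.0], nurse])
    roles = ("oocyte",) + ("nurse",) * 15
    return GermlineCyst(roles=roles, volume_fractions=tuple(fractions))


def _genotype_rules(area, genotype, config):
    """Per-genotype overrides: (eya_mode, fates_mode, foc, hetero, angle_eya)."""
    t = area_to_time(area)
    foc = oocyte_fraction_wt(area)
    hetero = config.nurse_heterogeneity
    eya_mode = "wt"
    fate_mode = "wt"
    if genotype == "gr1_eyaRNAi" and area >= config.critical_size_gr1:
        eya_mode = "low"
        hetero = config.nurse_heterogeneity * 3.5
        s = _smoothstep((area - config.critical_size_gr1) / 20000.0)
        foc = float(1 / 16 + (OOCYTE_PLATEAU - 1 / 16) * s)
    elif genotype == "tj_egfr" and area >= 6500.0:
        eya_mode = "low"
        fate_mode = "no_afc"
        s = _smoothstep((area - 6500.0) / (38000.0 - 6500.0))
        foc = float(1 / 16 + (0.55 - 1 / 16) * s)
    elif genotype == "mirr_eya" and area >= config.critical_size_mirr:
        eya_mode = "mirr_ectopic"
        # retained nurse-cell contact of MBFCs stalls further FC transition
        foc = min(foc, oocyte_fraction_wt(config.critical_size_mirr) + 0.05)
    return eya_mode, fate_mode, foc, hetero, t


_SCHEDULES = None


def _schedules():
    global _SCHEDULES
    if _SCHEDULES is None:
        _SCHEDULES = default_schedules()
    return _SCHEDULES


def _row_eya(row: int, t: float) -> float:
    sched = _schedules()
    return float(sched[min(row, 7)](t))


def generate_chamber(
    area: float,
    genotype: str = "wt",
    seed: int = 0,
    config: GeneratorConfig | None = None,
) -> EggChamberGeometry:
    """One synthetic egg chamber at the given germline section area (µm^2)."""
    config = config or GeneratorConfig()
    if genotype not in GENOTYPES:
        raise ValueError(f"unknown genotype {genotype!r}")
    lo, hi = config.area_range
    if not lo <= area <= hi:
        raise ValueError(f"area {area} outside configured range {config.area_range}")

    rng = np.random.default_rng(seed)
    eya_mode, fate_mode, foc, hetero, t = _genotype_rules(area, genotype, config)
    aspect = _aspect_ratio(area, config.phase1_aspect_ratio)
    a, b = _ellipse_axes(area, aspect)

    # outer contour (dense, for sub-0.5% polygon-area accuracy)
    m = 1440
    th = np.linspace(0.0, 2 * np.pi, m, endpoint=False)
    radial = np.ones(m)
    if config.noise_cv > 0:
        # smooth low-order shape noise (white vertex noise would self-intersect)
        for k in range(2, 9):
            amp = config.noise_cv * 0.06
            radial += rng.normal(0, amp) * np.cos(k * th) + rng.normal(
                0, amp
            ) * np.sin(k * th)
    contour = np.stack(
        [a * radial * np.cos(th), b * radial * np.sin(th)], axis=1
    )

    # oocyte cap: first locate the boundary row from the chord position,
    # then solve chord + interface-arc jointly for (area, angle)
    eta_chord = _solve_posterior_cap(a, b, foc * area)
    eta_tab, cum = _arc_table(a, b)
    half_p = cum[-1]
    u_chord = 1.0 - np.interp(eta_chord, eta_tab, cum) / half_p

    # Eya of the row overlying the nurse-cell--oocyte boundary
    d_rows = default_row_positions(t)
    row_at_b = int(np.argmin(np.abs(d_rows - u_chord))) + 1  # nearest row centre
    if eya_mode == "low":
        e_ncob = LOW_EYA
    elif eya_mode == "mirr_ectopic" and row_at_b >= 7:
        e_ncob = _row_eya(2, t)
    else:
        e_ncob = _row_eya(row_at_b, t)
    angle_true = float(90.0 + ANGLE_PER_EYA * (e_ncob - EYA_ZERO_AFFINITY))
    eta0, interface = _solve_interface(a, b, foc * area, angle_true)
    u_ncob = 1.0 - np.interp(eta0, eta_tab, cum) / half_p  # anterior distance

    # section FC layout: n_side rows per side, extents blend from uniform to
    # the matched state (6 tapered AFC rows over the nurse arc, the rest
    # sharing the oocyte arc)
    n_side = config.n_section_fcs // 2
    q = _flattening_progress(area)
    taper = np.linspace(1.35, 0.75, 6)
    e_final = np.empty(n_side)
    e_final[:6] = u_ncob * taper / taper.sum()
    e_final[6:] = (1.0 - u_ncob) / (n_side - 6)
    e_uniform = np.full(n_side, 1.0 / n_side)
    extents_u = (1 - q) * e_uniform + q * e_final  # normalized, sum 1
    d_mid = np.cumsum(extents_u) - extents_u / 2.0  # anterior distances

    # fates and Eya per row
    fates = np.array(
        ["AFC" if i < 6 else ("PFC" if d_mid[i] > 0.85 else "MBFC")
         for i in range(n_side)],
        dtype=object,
    )
    if fate_mode == "no_afc":
        fates = np.where(fates == "AFC", "MBFC", fates)
    eya = np.array([_row_eya(i + 1, t) for i in range(n_side)])
    if eya_mode == "low":
        eya = np.full(n_side, LOW_EYA)
    elif eya_mode == "mirr_ectopic":
        eya[fates == "MBFC"] = _row_eya(2, t)  # MBFC-driver domain
    if config.noise_cv > 0:
        eya = eya * np.exp(rng.normal(0.0, config.noise_cv, n_side))

    # mirror the two sides into full-contour arc-length coordinates
    pos_upper = d_mid * half_p
    pos_lower = 2 * half_p - pos_upper[::-1]
    fc_positions = np.concatenate([pos_upper, pos_lower])
    fc_extents = np.concatenate([extents_u, extents_u[::-1]]) * half_p
    fc_fate = np.concatenate([fates, fates[::-1]])
    fc_eya = np.concatenate([eya, eya[::-1]])

    # FC counts in 3-D (mitotic arrest at the end of phase 1)
    growth = min(1.0, (area / 6500.0) ** 0.8)
    fc_total = int(round(config.fc_count_at_arrest * growth))
    afc_3d = int(round(config.afc_fraction * config.fc_count_at_arrest))

    # sectioned nurse cells: 7 visible, area fractions from a seeded cyst
    cyst = generate_cyst(int(rng.integers(2**31)), hetero)
    nc_vols = cyst.nurse_fractions[:7]
    nc_area = nc_vols ** (2.0 / 3.0)
    nc_area = nc_area / nc_area.sum()
    nc_iface = nc_area * np.exp(
        rng.normal(0.0, hetero, nc_area.size) if hetero > 0 else 0.0
    )
    nc_iface = nc_iface / nc_iface.sum()

    return EggChamberGeometry(
        outer_contour=contour,
        aspect_ratio_AP=aspect,
        germline_area=float(area),
        oocyte_area=float(foc * area),
        nc_oocyte_interface=interface,
        triple_eta=float(eta0),
        fc_positions=fc_positions,
        fc_extents=fc_extents,
        fc_fate=fc_fate,
        fc_eya=fc_eya,
        fc_total_count_3d=fc_total,
        afc_count_3d=afc_3d,
        interface_angle_true=angle_true,
        nc_section_area_fractions=nc_area,
        nc_section_interface_fractions=nc_iface,
        genotype=genotype,
        semi_axes=(float(a), float(b)),
        time_h=t,
    )


def generate_cohort(config: GeneratorConfig) -> list[EggChamberGeometry]:
    """A seeded cohort of chambers with areas spanning all three phases.

    Areas are sampled log-uniformly over the configured range; the root
    seed is split into one independent stream per chamber.
    """
    if config.n_chambers < 1:
        raise ValueError("n_chambers must be at least 1")
    ss = np.random.SeedSequence(config.seed)
    area_rng = np.random.default_rng(ss.spawn(1)[0])
    lo, hi = config.area_range
    areas = np.exp(area_rng.uniform(np.log(lo), np.log(hi), config.n_chambers))
    chambers = []
    child_seeds = ss.spawn(config.n_chambers + 1)[1:]
    for i, (area, cs) in enumerate(zip(areas, child_seeds)):
        g = generate_chamber(
            float(area),
            genotype=config.genotype,
            seed=int(cs.generate_state(1)[0] % (2**31)),
            config=config,
        )
        g.chamber_id = i
        chambers.append(g)
    return chambers


def cohort_tables(
    chambers: Sequence[EggChamberGeometry],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-chamber morphometric table and per-FC table for a cohort."""
    from .morphometrics import measure, record_to_dict

    rows, fc_rows = [], []
    for g in chambers:
        rec = measure(g)
        rows.append(record_to_dict(rec, chamber_id=g.chamber_id))
        for j in range(g.fc_positions.size):
            fc_rows.append(
                {
                    "chamber_id": g.chamber_id,
                    "arc_position_um": g.fc_positions[j],
                    "fate": g.fc_fate[j],
                    "eya": g.fc_eya[j],
                    "apical_extent_um": g.fc_extents[j],
                }
            )
    return pd.DataFrame(rows), pd.DataFrame(fc_rows)
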