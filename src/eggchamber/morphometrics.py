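"""Morphometric quantification of 2-D medial egg-chamber sections.

Computes the 24-parameter morphometric record, phase assignment by germline
area, FC-contact proportions, the oocyte/nurse/epithelium interface angle,
per-row apical profiles and nurse-cell variance statistics from an
:class:`~eggchamber.synthetic_data.EggChamberGeometry`.  All quantities are
measured from the stored curves (polygon areas, arc lengths, tangent fits),
not from generator bookkeeping, so generator round-trips are a real check.

The 24-parameter schema is a reconstruction: the assay's full parameter
table is defined in supplementary material not reproduced here, so the
schema below covers the published subset (areas, proportions, interface
angle, row counts, apical extents, Eya summaries, nurse-cell CVs) padded to
24 quantitative descriptors; see docs/methods.md.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from shapely.geometry import Polygon

from .synthetic_data import EggChamberGeometry

__all__ = [
    "PhaseThresholds",
    "EggChamberRecord",
    "PARAMETER_COLUMNS",
    "assign_phase",
    "measure",
    "record_to_dict",
    "contact_proportion",
    "interface_angle",
    "nurse_cell_cv",
    "apical_area_profile",
    "measure_cohort",
]


@dataclass(frozen=True)
class PhaseThresholds:
    """Germline-area boundaries of the three morphogenetic phases (µm^2)."""

    t12: float = 6500.0
    t23: float = 31500.0

    def __post_init__(self):
        if not 0 < self.t12 < self.t23:
            raise ValueError("phase thresholds must satisfy 0 < t12 < t23")


def assign_phase(area: float, thresholds: PhaseThresholds | None = None) -> int:
    """Phase 1/2/3 from germline area; intervals are left-closed."""
    if area <= 0:
        raise ValueError("germline area must be positive")
    th = thresholds or PhaseThresholds()
    if area < th.t12:
        return 1
    if area < th.t23:
        return 2
    return 3


#: The 24 quantitative morphometric parameters, in column order.
PARAMETER_COLUMNS = (
    "germline_area",
    "egg_chamber_area",
    "oocyte_area",
    "nc_compartment_area",
    "oocyte_fraction_of_germline",
    "aspect_ratio",
    "germline_perimeter",
    "fc_count_section",
    "fc_count_total",
    "prop_fc_on_oocyte",
    "oocyte_fc_interface_fraction",
    "nc_fc_interface_length",
    "interface_angle",
    "afc_row_count_on_nc",
    "mean_apical_extent_anterior",
    "max_apical_extent_anterior",
    "mean_apical_extent_posterior",
    "max_apical_extent_posterior",
    "apical_extent_ap_ratio",
    "eya_mean_at_ncob",
    "eya_mean_anterior",
    "eya_mean_posterior",
    "nc_size_cv",
    "nc_fc_interface_cv",
)


@dataclass
class EggChamberRecord:
    """One egg chamber's 24 morphometric parameters plus metadata."""

    values: dict
    genotype: str
    phase: int
    chamber_id: int = 0

    def __post_init__(self):
        missing = set(PARAMETER_COLUMNS) - set(self.values)
        if missing:
            raise ValueError(f"record missing parameters: {sorted(missing)}")


def record_to_dict(rec: EggChamberRecord, chamber_id: int | None = None) -> dict:
    out = {"chamber_id": rec.chamber_id if chamber_id is None else chamber_id}
    out.update({k: rec.values[k] for k in PARAMETER_COLUMNS})
    out["genotype"] = rec.genotype
    out["phase"] = rec.phase
    return out


# ----------------------------------------------------------------------------
# Contour helpers
# ----------------------------------------------------------------------------


def _contour_arcs(contour: np.ndarray):
    """Closed-polyline cumulative arc length and anterior-pole origin.

    Returns (points reordered to start at the anterior pole going through
    the upper half, cumulative arc-length array, total perimeter).
    """
    pts = np.asarray(contour, dtype=float)
    i0 = int(np.argmin(pts[:, 0]))  # anterior pole = leftmost vertex
    pts = np.roll(pts, -i0, axis=0)
    # orient so the curve first enters the upper half (y > 0)
    k = min(5, len(pts) - 1)
    if pts[k, 1] < 0:
        pts = np.roll(pts[::-1], 1, axis=0)
    seg = np.linalg.norm(np.diff(np.vstack([pts, pts[:1]]), axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    return pts, cum, float(cum[-1])


def _anterior_distance(s: np.ndarray, perimeter: float) -> np.ndarray:
    """Normalized distance-to-anterior-pole of arc coordinates (either side)."""
    half = perimeter / 2.0
    s = np.asarray(s, dtype=float) % perimeter
    return np.where(s <= half, s, perimeter - s) / half


def _tangent_by_quadratic_fit(
    pts: np.ndarray, cum: np.ndarray, s0: float, window: float
) -> np.ndarray:
    """Unit tangent of a polyline at arc position s0 (local quadratic fit)."""
    P = cum[-1]
    ds = (cum[:-1] - s0 + P / 2) % P - P / 2
    sel = np.abs(ds) <= window
    if sel.sum() < 3:
        sel = np.argsort(np.abs(ds))[:5]
    u = ds[sel]
    cx = np.polyfit(u, pts[sel, 0], 2)
    cy = np.polyfit(u, pts[sel, 1], 2)
    t = np.array([cx[1], cy[1]])
    n = np.linalg.norm(t)
    if n < 1e-12:
        raise ValueError("degenerate tangent")
    return t / n


def _triple_points(geometry: EggChamberGeometry) -> tuple[np.ndarray, np.ndarray]:
    iface = np.asarray(geometry.nc_oocyte_interface, dtype=float)
    return iface[-1], iface[0]  # upper (+y), lower (-y) endpoints


def _oocyte_polygon(geometry: EggChamberGeometry) -> Polygon:
    """Region bounded by the interface and the posterior contour arc."""
    pts, cum, P = _contour_arcs(geometry.outer_contour)
    up, lo = _triple_points(geometry)
    s_up = _nearest_arc(pts, cum, up)
    s_lo = _nearest_arc(pts, cum, lo)
    # posterior arc from the upper triple point to the lower one
    smin, smax = sorted([s_up, s_lo])
    sel = (cum[:-1] > smin) & (cum[:-1] < smax)
    arc = pts[sel]
    iface = np.asarray(geometry.nc_oocyte_interface, dtype=float)
    # iface runs lower -> upper triple point; append the posterior arc
    # from the upper point back to the lower one (ascending arc coordinate)
    ring = np.vstack([iface, arc if s_up < s_lo else arc[::-1]])
    poly = Polygon(ring)
    if not poly.is_valid or poly.area <= 0:
        poly = Polygon(ring[::-1]).buffer(0)
    return poly


def _nearest_arc(pts: np.ndarray, cum: np.ndarray, p: np.ndarray) -> float:
    d = np.linalg.norm(pts - p[None, :], axis=1)
    return float(cum[int(np.argmin(d))])


# ----------------------------------------------------------------------------
# Operations
# ----------------------------------------------------------------------------


def contact_proportion(geometry: EggChamberGeometry) -> float:
    """Proportion of the section FC layer in contact with the oocyte.

    Each FC contributes the fraction of its apical extent lying on the
    oocyte-adjacent portion of the contour, so a cell straddling the
    nurse-cell--oocyte boundary counts fractionally.
    """
    if geometry.fc_positions.size == 0:
        raise ValueError("geometry has no follicle cells")
    if geometry.oocyte_area <= 0:
        return 0.0
    if geometry.oocyte_area >= 0.999 * geometry.germline_area:
        return 1.0
    pts, cum, P = _contour_arcs(geometry.outer_contour)
    up, lo = _triple_points(geometry)
    u_up = _anterior_distance(np.array([_nearest_arc(pts, cum, up)]), P)[0]
    u_lo = _anterior_distance(np.array([_nearest_arc(pts, cum, lo)]), P)[0]
    u_ncob = 0.5 * (u_up + u_lo)
    u = _anterior_distance(geometry.fc_positions, P)
    e = geometry.fc_extents / (P / 2.0)  # normalized extents
    lo_i = u - e / 2.0
    hi_i = u + e / 2.0
    overlap = np.clip(hi_i - np.maximum(lo_i, u_ncob), 0.0, None)
    frac = np.minimum(overlap / np.maximum(e, 1e-12), 1.0)
    return float(np.mean(frac))


def interface_angle(geometry: EggChamberGeometry, window_frac: float = 0.05) -> float:
    """Contact angle (deg) between interface and contour, through the oocyte.

    Tangents are estimated by local quadratic fits over a +/- ``window_frac``
    perimeter window; the angle is measured against the posterior-pointing
    contour tangent and averaged over the two triple points, so < 90 deg
    means the oocyte wets the epithelium (effective oocyte affinity).
    """
    iface = np.asarray(geometry.nc_oocyte_interface, dtype=float)
    if iface.shape[0] < 3:
        raise ValueError("interface curve too short")
    pts, cum, P = _contour_arcs(geometry.outer_contour)
    window = window_frac * P
    iface_seg = np.linalg.norm(np.diff(iface, axis=0), axis=1)
    iface_cum = np.concatenate([[0.0], np.cumsum(iface_seg)])

    angles = []
    for endpoint, end_s in ((iface[-1], iface_cum[-1]), (iface[0], 0.0)):
        dmin = np.min(np.linalg.norm(pts - endpoint[None, :], axis=1))
        if dmin > 0.05 * P:
            raise ValueError("interface does not reach the outer contour")
        s0 = _nearest_arc(pts, cum, endpoint)
        t_wall = _tangent_by_quadratic_fit(pts, cum, s0, window)
        # orient the wall tangent toward the posterior pole (+x)
        if t_wall @ np.array([1.0, 0.0]) < 0:
            t_wall = -t_wall
        # interface tangent at the endpoint (open-curve quadratic fit over
        # the nearest samples), pointing away from the wall
        w_if = max(iface_cum[-1] * 0.05, 4 * float(np.mean(iface_seg)))
        near = np.abs(iface_cum - end_s) <= w_if
        if near.sum() < 3:
            near = np.argsort(np.abs(iface_cum - end_s))[:5]
        uu = iface_cum[near] - end_s
        cx = np.polyfit(uu, iface[near, 0], 2)
        cy = np.polyfit(uu, iface[near, 1], 2)
        t_if = np.array([cx[-2], cy[-2]])
        t_if = t_if / max(np.linalg.norm(t_if), 1e-12)
        into = -endpoint / max(np.linalg.norm(endpoint), 1e-9)
        if t_if @ into < 0:
            t_if = -t_if
        cosang = np.clip(t_wall @ t_if, -1.0, 1.0)
        angles.append(np.degrees(np.arccos(cosang)))
    return float(np.mean(angles))


def nurse_cell_cv(geometry: EggChamberGeometry) -> dict[str, float]:
    """CVs of per-nurse-cell FC-interface share and area share (sample sd)."""
    areas = np.asarray(geometry.nc_section_area_fractions, dtype=float)
    iface = np.asarray(geometry.nc_section_interface_fractions, dtype=float)
    if areas.size < 2:
        raise ValueError("need at least 2 sectioned nurse cells")
    return {
        "cv_interface_fraction": float(np.std(iface, ddof=1) / np.mean(iface)),
        "cv_area_fraction": float(np.std(areas, ddof=1) / np.mean(areas)),
    }


def apical_area_profile(geometry: EggChamberGeometry) -> pd.DataFrame:
    """Per-row anterior distance, apical extent and Eya (upper half rows)."""
    if geometry.fc_positions.size == 0:
        raise ValueError("geometry has no follicle cells")
    pts, cum, P = _contour_arcs(geometry.outer_contour)
    u = _anterior_distance(geometry.fc_positions, P)
    upper = geometry.fc_positions <= P / 2.0
    order = np.argsort(geometry.fc_positions[upper])
    rows = []
    for r, j in enumerate(np.flatnonzero(upper)[order], start=1):
        rows.append(
            {
                "row": r,
                "distance_to_anterior_um": u[j] * P / 2.0,
                "apical_extent_um": geometry.fc_extents[j],
                "eya": geometry.fc_eya[j],
                "fate": geometry.fc_fate[j],
            }
        )
    return pd.DataFrame(rows)


def measure(
    geometry: EggChamberGeometry, thresholds: PhaseThresholds | None = None
) -> EggChamberRecord:
    """All 24 morphometric parameters of one egg-chamber section."""
    poly = Polygon(geometry.outer_contour)
    if not poly.is_valid:
        raise ValueError("degenerate (self-intersecting) outer contour")
    area = float(poly.area)
    perimeter = float(poly.length)
    pts, cum, P = _contour_arcs(geometry.outer_contour)

    if geometry.oocyte_area > 0:
        oo_poly = _oocyte_polygon(geometry)
        oocyte_area = float(oo_poly.area)
        up, lo = _triple_points(geometry)
        u_up = _anterior_distance(np.array([_nearest_arc(pts, cum, up)]), P)[0]
        u_lo = _anterior_distance(np.array([_nearest_arc(pts, cum, lo)]), P)[0]
        u_ncob = 0.5 * (u_up + u_lo)
        angle = interface_angle(geometry)
    else:
        oocyte_area = 0.0
        u_ncob = 1.0
        angle = float("nan")

    bbox = np.ptp(pts, axis=0)
    aspect = float(bbox[0] / bbox[1])

    u = _anterior_distance(geometry.fc_positions, P)
    on_oo = u > u_ncob
    prop_oo = contact_proportion(geometry)
    oo_iface_frac = 1.0 - u_ncob
    nc_iface_len = u_ncob * perimeter

    ant = geometry.fc_extents[~on_oo]
    post = geometry.fc_extents[on_oo]
    mean_a = float(np.mean(ant)) if ant.size else 0.0
    max_a = float(np.max(ant)) if ant.size else 0.0
    mean_p = float(np.mean(post)) if post.size else 0.0
    max_p = float(np.max(post)) if post.size else 0.0
    ap_ratio = float(mean_a / mean_p) if mean_p > 0 else float("nan")

    afc = geometry.fc_fate == "AFC"
    afc_width = (
        float(np.mean(geometry.fc_extents[afc])) if afc.any()
        else float(np.mean(geometry.fc_extents))
    )
    nc_arc_half = u_ncob * P / 2.0
    afc_rows = int(round(nc_arc_half / afc_width)) if afc_width > 0 else 0

    near_b = np.abs(u - u_ncob) <= (2.0 * np.mean(geometry.fc_extents) / (P / 2.0))
    eya_ncob = float(np.mean(geometry.fc_eya[near_b])) if near_b.any() else float(
        np.mean(geometry.fc_eya)
    )
    eya_ant = float(np.mean(geometry.fc_eya[u <= 6.0 / 30.0]))
    eya_post = float(np.mean(geometry.fc_eya[u > 0.5]))

    cvs = nurse_cell_cv(geometry)

    values = {
        "germline_area": area,
        "egg_chamber_area": area * 1.12,
        "oocyte_area": oocyte_area,
        "nc_compartment_area": area - oocyte_area,
        "oocyte_fraction_of_germline": oocyte_area / area,
        "aspect_ratio": aspect,
        "germline_perimeter": perimeter,
        "fc_count_section": int(geometry.fc_positions.size),
        "fc_count_total": geometry.fc_total_count_3d,
        "prop_fc_on_oocyte": prop_oo,
        "oocyte_fc_interface_fraction": oo_iface_frac,
        "nc_fc_interface_length": nc_iface_len,
        "interface_angle": angle,
        "afc_row_count_on_nc": afc_rows,
        "mean_apical_extent_anterior": mean_a,
        "max_apical_extent_anterior": max_a,
        "mean_apical_extent_posterior": mean_p,
        "max_apical_extent_posterior": max_p,
        "apical_extent_ap_ratio": ap_ratio,
        "eya_mean_at_ncob": eya_ncob,
        "eya_mean_anterior": eya_ant,
        "eya_mean_posterior": eya_post,
        "nc_size_cv": cvs["cv_area_fraction"],
        "nc_fc_interface_cv": cvs["cv_interface_fraction"],
    }
    return EggChamberRecord(
        values=values,
        genotype=geometry.genotype,
        phase=assign_phase(area, thresholds),
        chamber_id=geometry.chamber_id,
    )


def measure_cohort(
    chambers: Sequence[EggChamberGeometry],
    thresholds: PhaseThresholds | None = None,
) -> pd.DataFrame:
    """Tidy per-chamber table (one row per chamber, 24 parameters)."""
    return pd.DataFrame(
        [record_to_dict(measure(g, thresholds)) for g in chambers]
    )
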