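"""Eya expression dynamics and their translation into affinity inputs.

Follicle-cell (FC) Eya levels, measured per anterior cell row over the
36-hour developmental window covering stages 5-10b, act as the proxy for
cell-cell affinity in both phase-field models:

* the FC model maps Eya linearly to a non-negative contact-energy reward
  for the nurse-cell (affine) boundary compartment;
* the germline model maps Eya to a *signed* effective affinity of germline
  cells for the epithelium, with 72 arb. unit as the zero-crossing -- above
  72 the nurse compartment effectively wets the epithelium, below 72 the
  oocyte does.

Row dynamics are represented as 6th-order polynomials in time constrained
to have vanishing derivatives at t = 0 and t = 36 h, fitted to per-stage
mean intensities placed at stage midpoints.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.linalg import null_space

__all__ = [
    "T_END_H",
    "PHASE_T12_H",
    "PHASE_T23_H",
    "EYA_ZERO_AFFINITY",
    "DEFAULT_STAGE_DURATIONS_H",
    "DEFAULT_STAGE_MEANS",
    "DEFAULT_KAPPA_FC",
    "DEFAULT_KAPPA_GERMLINE",
    "stage_midpoints",
    "EyaSchedule",
    "ConstantSchedule",
    "PiecewiseSchedule",
    "ScenarioSpec",
    "fit_schedule",
    "default_schedules",
    "eya_to_affinity",
    "scenario",
    "default_row_positions",
    "AffinityField",
    "boundary_affinity_field",
    "schedules_to_csv",
    "schedules_from_csv",
]

# ----------------------------------------------------------------------------
# Constants of the developmental clock
# ----------------------------------------------------------------------------

#: Length of the modelled developmental window (start of stage 5 to end of
#: stage 10b), hours.
T_END_H = 36.0

#: Eya intensity (arb. unit) at which the effective germline affinity is zero.
EYA_ZERO_AFFINITY = 72.0

#: Stage durations in hours for stages 5-10b.  The published per-stage
#: durations vary between sources; these defaults are standard literature
#: values rounded to sum exactly to the 36 h window and are editable
#: (pass your own table to :func:`fit_schedule` / :func:`stage_midpoints`).
DEFAULT_STAGE_DURATIONS_H: dict[str, float] = {
    "5": 6.0,
    "6": 5.0,
    "7": 5.0,
    "8": 5.0,
    "9e": 3.5,
    "9m": 3.5,
    "10a": 4.0,
    "10b": 4.0,
}

#: Morphogenetic phase boundaries on the simulation clock: mid stage 7 and
#: mid stage 10a.
PHASE_T12_H = 13.5
PHASE_T23_H = 30.0

#: Default per-row Eya stage means (arb. unit), rows 1-7 x stages 5-10b.
#: A synthetic family: uniform high expression through phase 1, an
#: anterior-to-posterior gradient developing through phase 2, and by phase 3
#: a strict segregation with rows 1-6 above the 72-unit zero point and row 7
#: (the anterior-most main-body row, standing in for rows 7-14) well below it.
#: Values are monotone non-increasing in row index at every stage.
DEFAULT_STAGE_MEANS: pd.DataFrame = pd.DataFrame(
    {
        "5":   [150.0, 148.0, 146.0, 145.0, 143.0, 142.0, 140.0],
        "6":   [152.0, 148.0, 145.0, 142.0, 140.0, 138.0, 135.0],
        "7":   [155.0, 146.0, 138.0, 130.0, 122.0, 115.0, 110.0],
        "8":   [158.0, 140.0, 125.0, 110.0, 95.0, 88.0, 60.0],
        "9e":  [160.0, 135.0, 115.0, 100.0, 88.0, 82.0, 40.0],
        "9m":  [160.0, 130.0, 110.0, 95.0, 84.0, 80.0, 30.0],
        "10a": [158.0, 128.0, 105.0, 92.0, 82.0, 79.0, 25.0],
        "10b": [155.0, 125.0, 100.0, 90.0, 80.0, 78.0, 20.0],
    },
    index=pd.Index(range(1, 8), name="row"),
)

#: Calibration constant for the FC model Eya -> affinity map
#: (contact-energy reward per arb. unit), fixed once against the wild-type
#: 14-cell scenario.
DEFAULT_KAPPA_FC = 0.012

#: Calibration constant for the germline model Eya -> signed effective
#: affinity map (boundary energy per unit length per arb. unit), fixed once
#: against the wild-type germline scenario.
DEFAULT_KAPPA_GERMLINE = 1.5e-3


def stage_midpoints(
    stage_durations: Mapping[str, float] | None = None,
) -> pd.Series:
    """Midpoint time (hours after start of stage 5) of each stage."""
    durations = dict(stage_durations or DEFAULT_STAGE_DURATIONS_H)
    names = list(durations)
    vals = np.asarray([durations[s] for s in names], dtype=float)
    if np.any(vals <= 0):
        raise ValueError("stage durations must be positive")
    ends = np.cumsum(vals)
    mids = ends - vals / 2.0
    return pd.Series(mids, index=pd.Index(names, name="stage"), name="t_mid")


# ----------------------------------------------------------------------------
# Schedule objects
# ----------------------------------------------------------------------------


def _smoothstep(x: np.ndarray | float) -> np.ndarray | float:
    x = np.clip(x, 0.0, 1.0)
    return x * x * (3.0 - 2.0 * x)


@dataclass(frozen=True)
class EyaSchedule:
    """6th-order polynomial Eya(t) on t in [0, 36] h.

    The polynomial has vanishing derivative at both domain endpoints and its
    values are clipped at zero on evaluation.
    """

    row: int
    coefficients: tuple[float, ...]  # c0..c6, Eya = sum c_k t^k
    domain: tuple[float, float] = (0.0, T_END_H)

    def __post_init__(self) -> None:
        if len(self.coefficients) != 7:
            raise ValueError("an Eya schedule has exactly 7 coefficients")
        c = np.asarray(self.coefficients, dtype=float)
        k = np.arange(7, dtype=float)
        for t in self.domain:
            dp = float(np.sum(k[1:] * c[1:] * t ** (k[1:] - 1)))
            scale = max(1.0, float(np.max(np.abs(c))) * max(1.0, t) ** 5)
            if abs(dp) > 1e-8 * scale:
                raise ValueError(
                    f"schedule derivative at t={t} is {dp:.3g}, not 0"
                )

    def __call__(self, t: np.ndarray | float) -> np.ndarray | float:
        t = np.clip(t, *self.domain)
        c = np.asarray(self.coefficients, dtype=float)
        val = np.polynomial.polynomial.polyval(t, c)
        return np.maximum(val, 0.0)


@dataclass(frozen=True)
class ConstantSchedule:
    """Flat Eya level, used for knockdown / ectopic-expression overrides."""

    value: float
    row: int = 0
    domain: tuple[float, float] = (0.0, T_END_H)

    def __call__(self, t: np.ndarray | float) -> np.ndarray | float:
        return np.maximum(np.full_like(np.asarray(t, dtype=float), self.value), 0.0)


@dataclass(frozen=True)
class PiecewiseSchedule:
    """Switch from one schedule to another at ``t_switch`` (hours).

    A short smoothing window avoids a discontinuous affinity input to the
    solvers.
    """

    t_switch: float
    before: Callable[[float], float]
    after: Callable[[float], float]
    smooth_h: float = 1.0
    row: int = 0
    domain: tuple[float, float] = (0.0, T_END_H)

    def __call__(self, t: np.ndarray | float) -> np.ndarray | float:
        t = np.asarray(t, dtype=float)
        w = _smoothstep((t - self.t_switch) / self.smooth_h + 0.5)
        return (1.0 - w) * np.asarray(self.before(t)) + w * np.asarray(self.after(t))


Schedule = Callable[[float], float]


@dataclass
class ScenarioSpec:
    """A named perturbation of the per-row affinity schedules.

    ``model`` selects which solver the scenario addresses ('fc' = 14-cell
    follicle-cell model, 'germline' = two-compartment germline model);
    ``schedules`` maps every modelled row to its (possibly overridden)
    Eya schedule; ``overrides`` records which rows were substituted.
    """

    model: str
    name: str
    schedules: dict[int, Schedule]
    overrides: dict[int, str] = field(default_factory=dict)

    def eya(self, row: int, t: np.ndarray | float) -> np.ndarray | float:
        return self.schedules[row](t)

    def to_json(self) -> str:
        return json.dumps(
            {
                "model": self.model,
                "name": self.name,
                "rows": sorted(self.schedules),
                "overrides": {str(k): v for k, v in self.overrides.items()},
            },
            indent=2,
        )


# ----------------------------------------------------------------------------
# Constrained polynomial fit
# ----------------------------------------------------------------------------


def fit_schedule(
    stage_means: pd.DataFrame | Sequence[tuple[str, float]],
    stage_durations: Mapping[str, float] | None = None,
    row: int = 0,
) -> EyaSchedule:
    """Fit the constrained 6th-order Eya polynomial for one cell row.

    Parameters
    ----------
    stage_means
        Table with columns ``stage`` and ``mean_eya`` (or a sequence of
        ``(stage, mean)`` pairs).  Intensities are assigned to the midpoint
        of each stage.
    stage_durations
        Stage -> duration (hours); must be positive and sum to 36 h.
    row
        Row label carried on the returned schedule.

    The fit is linear least squares over 6th-order polynomials subject to
    p'(0) = p'(36) = 0, solved in the null space of the two derivative
    constraints.  Fitting is done on the scaled time u = t/36 for
    conditioning; stored coefficients are in hours.
    """
    if isinstance(stage_means, pd.DataFrame):
        pairs = list(zip(stage_means["stage"], stage_means["mean_eya"]))
    else:
        pairs = list(stage_means)
    if len(pairs) < 7:
        raise ValueError(
            f"need at least 7 stage means for a constrained 6th-order fit, got {len(pairs)}"
        )
    durations = dict(stage_durations or DEFAULT_STAGE_DURATIONS_H)
    total = sum(durations.values())
    if not np.isclose(total, T_END_H, atol=1e-6):
        raise ValueError(f"stage durations must sum to {T_END_H} h, got {total}")
    mids = stage_midpoints(durations)
    t = np.asarray([mids[s] for s, _ in pairs], dtype=float)
    y = np.asarray([m for _, m in pairs], dtype=float)

    u = t / T_END_H
    A = np.vander(u, 7, increasing=True)
    # derivative constraints at u = 0 and u = 1
    k = np.arange(7, dtype=float)
    C = np.zeros((2, 7))
    C[0, 1] = 1.0
    C[1, 1:] = k[1:]  # sum k * b_k * 1^(k-1)
    N = null_space(C)  # 7 x 5
    AN = A @ N
    z, *_ = np.linalg.lstsq(AN, y, rcond=None)
    b = N @ z
    c = b / T_END_H ** k
    return EyaSchedule(row=row, coefficients=tuple(c))


def default_schedules(
    stage_means: pd.DataFrame | None = None,
    stage_durations: Mapping[str, float] | None = None,
) -> dict[int, EyaSchedule]:
    """Fit the shipped per-row stage-means table into row schedules (rows 1-7)."""
    means = stage_means if stage_means is not None else DEFAULT_STAGE_MEANS
    out: dict[int, EyaSchedule] = {}
    for row in means.index:
        tbl = pd.DataFrame(
            {"stage": means.columns, "mean_eya": means.loc[row].to_numpy()}
        )
        out[int(row)] = fit_schedule(tbl, stage_durations, row=int(row))
    return out


# ----------------------------------------------------------------------------
# Eya -> affinity maps
# ----------------------------------------------------------------------------


def eya_to_affinity(
    E: np.ndarray | float,
    model: str,
    kappa_fc: float = DEFAULT_KAPPA_FC,
    kappa_germline: float = DEFAULT_KAPPA_GERMLINE,
) -> np.ndarray | float:
    """Map an Eya intensity to an affinity input for the named model.

    ``model='fc'``: non-negative, monotone increasing, a = kappa_fc * E.
    ``model='germline'``: signed, g = kappa_germline * (E - 72); positive g
    means effective nurse-cell affinity for the epithelium, negative g
    effective oocyte affinity.
    """
    E = np.asarray(E, dtype=float)
    if np.any(E < 0):
        raise ValueError("Eya intensities must be non-negative")
    if model == "fc":
        out = kappa_fc * E
    elif model == "germline":
        out = kappa_germline * (E - EYA_ZERO_AFFINITY)
    else:
        raise ValueError(f"unknown model {model!r}; expected 'fc' or 'germline'")
    return out if out.ndim else float(out)


# ----------------------------------------------------------------------------
# Scenarios
# ----------------------------------------------------------------------------

#: Eya level used for knockdown-like overrides (well below the 72-unit zero
#: point, matching the near-background levels of Eya-negative FCs).
LOW_EYA = 20.0

#: Eya level used for uniform ectopic-expression overrides (phase-1-like).
HIGH_EYA = 130.0

FC_SCENARIOS = ("wt", "uniform_high", "row3_kd", "rows6to8_ectopic")
GERMLINE_SCENARIOS = (
    "germline_wt",
    "premature_loss",
    "ectopic_nc_affinity",
    "all_negative",
)


def scenario(
    name: str, base_schedules: Mapping[int, Schedule] | None = None
) -> ScenarioSpec:
    """Build a named perturbation scenario from per-row base schedules.

    Base schedules must cover rows 1-7; for the 14-cell FC model the row-7
    dynamic is assigned to cells 7-14 (main-body and posterior rows).
    """
    base = dict(base_schedules) if base_schedules is not None else default_schedules()
    missing = [r for r in range(1, 8) if r not in base]
    if missing:
        raise ValueError(f"base schedules must cover rows 1-7, missing {missing}")

    if name in FC_SCENARIOS:
        rows = {r: base[min(r, 7)] for r in range(1, 15)}
        overrides: dict[int, str] = {}
        if name == "uniform_high":
            for r in range(1, 7):
                rows[r] = base[1]
                if r != 1:
                    overrides[r] = "row 1 dynamic"
        elif name == "row3_kd":
            rows[3] = ConstantSchedule(LOW_EYA, row=3)
            overrides[3] = f"constant {LOW_EYA}"
        elif name == "rows6to8_ectopic":
            for r in (6, 7, 8):
                rows[r] = base[2]
                overrides[r] = "row 2 dynamic"
        return ScenarioSpec(model="fc", name=name, schedules=rows, overrides=overrides)

    if name in GERMLINE_SCENARIOS:
        rows = {r: base[r] for r in range(1, 8)}
        overrides = {}
        if name == "premature_loss":
            # global Eya collapse already in phase 1
            for r in rows:
                rows[r] = ConstantSchedule(LOW_EYA, row=r)
                overrides[r] = f"constant {LOW_EYA}"
        elif name == "ectopic_nc_affinity":
            # uniformly Eya-positive epithelium in all phases
            for r in rows:
                rows[r] = ConstantSchedule(HIGH_EYA, row=r)
                overrides[r] = f"constant {HIGH_EYA}"
        elif name == "all_negative":
            # Eya-negative epithelium from phase 2 onwards
            for r in list(rows):
                rows[r] = PiecewiseSchedule(
                    t_switch=PHASE_T12_H,
                    before=base[r],
                    after=ConstantSchedule(LOW_EYA, row=r),
                    row=r,
                )
                overrides[r] = f"wt until t={PHASE_T12_H} h then constant {LOW_EYA}"
        return ScenarioSpec(
            model="germline", name=name, schedules=rows, overrides=overrides
        )

    raise ValueError(
        f"unknown scenario {name!r}; known: {FC_SCENARIOS + GERMLINE_SCENARIOS}"
    )


# ----------------------------------------------------------------------------
# Boundary affinity field for the germline model
# ----------------------------------------------------------------------------

#: Fractional posterior spread of FC row positions between the start of
#: phase 2 and the end of the window (anterior rows widen as they flatten,
#: pushing row boundaries toward the posterior).
DEFAULT_ROW_SPREAD = 0.45


def default_row_positions(t: np.ndarray | float, n_rows: int = 7) -> np.ndarray:
    """Normalized anterior-pole distances of FC rows 1..n_rows at time t.

    Rows start evenly spaced over the anterior half of the boundary (14 cell
    rows over [0, 1]) and spread posteriorly from the start of phase 2 to the
    end of the window as anterior rows expand their contact surfaces.
    """
    t = np.asarray(t, dtype=float)
    spread = 1.0 + DEFAULT_ROW_SPREAD * _smoothstep(
        (t - PHASE_T12_H) / (T_END_H - PHASE_T12_H)
    )
    r = np.arange(1, n_rows + 1, dtype=float)
    base = (r - 0.5) / 14.0
    return np.multiply.outer(spread, base) if t.ndim else spread * base


class AffinityField:
    """Signed effective affinity g(s, t) along the germline boundary.

    ``s`` is normalized arc-length distance from the anterior pole (0) to the
    posterior pole (1).  Row affinities are linearly interpolated at their
    time-dependent positions; anterior of row 1 the row-1 value applies, and
    posterior of row 7 the (Eya-negative in later phases) row-7 value applies.
    """

    def __init__(
        self,
        schedules: Mapping[int, Schedule],
        row_positions: Callable[[float], np.ndarray] | pd.DataFrame | None = None,
        kappa_germline: float = DEFAULT_KAPPA_GERMLINE,
    ):
        self.schedules = {int(r): schedules[r] for r in sorted(schedules)}
        self.rows = sorted(self.schedules)
        self.kappa = kappa_germline
        if row_positions is None:
            self._positions = lambda t: default_row_positions(t, len(self.rows))
        elif isinstance(row_positions, pd.DataFrame):
            self._positions = self._interp_positions(row_positions)
        else:
            self._positions = row_positions
        # validate monotonicity on a time grid
        for t in np.linspace(0.0, T_END_H, 13):
            d = np.asarray(self._positions(t), dtype=float)
            if d.shape != (len(self.rows),):
                raise ValueError("row_positions must return one distance per row")
            if np.any(d < 0) or np.any(d > 1):
                raise ValueError("row positions must lie in [0, 1]")
            if np.any(np.diff(d) <= 0):
                raise ValueError(f"row positions not strictly increasing at t={t}")

    def _interp_positions(self, table: pd.DataFrame):
        tbl = table.sort_values(["row", "t"])
        rows = sorted(tbl["row"].unique())
        series = {
            r: (g["t"].to_numpy(float), g["distance"].to_numpy(float))
            for r, g in tbl.groupby("row")
        }

        def positions(t: float) -> np.ndarray:
            return np.asarray([np.interp(t, *series[r]) for r in rows])

        return positions

    def row_affinities(self, t: float) -> np.ndarray:
        E = np.asarray([self.schedules[r](t) for r in self.rows], dtype=float)
        return self.kappa * (E - EYA_ZERO_AFFINITY)

    def __call__(self, s: np.ndarray | float, t: float) -> np.ndarray | float:
        s_arr = np.asarray(s, dtype=float)
        d = np.asarray(self._positions(t), dtype=float)
        a = self.row_affinities(t)
        out = np.interp(s_arr, d, a)  # constant extrapolation at both ends
        return out if s_arr.ndim else float(out)


def boundary_affinity_field(
    schedules: Mapping[int, Schedule],
    row_positions: Callable[[float], np.ndarray] | pd.DataFrame | None = None,
    kappa_germline: float = DEFAULT_KAPPA_GERMLINE,
) -> AffinityField:
    """Build the continuous boundary affinity map g(s, t) from row schedules."""
    return AffinityField(schedules, row_positions, kappa_germline)


# ----------------------------------------------------------------------------
# Schedule IO
# ----------------------------------------------------------------------------


def schedules_to_csv(schedules: Mapping[int, EyaSchedule], path) -> None:
    rows = []
    for r in sorted(schedules):
        sched = schedules[r]
        rows.append({"row": r, **{f"c{k}": sched.coefficients[k] for k in range(7)}})
    pd.DataFrame(rows).to_csv(path, index=False)


def schedules_from_csv(path) -> dict[int, EyaSchedule]:
    df = pd.read_csv(path)
    return {
        int(rec["row"]): EyaSchedule(
            row=int(rec["row"]),
            coefficients=tuple(float(rec[f"c{k}"]) for k in range(7)),
        )
        for rec in df.to_dict("records")
    }
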