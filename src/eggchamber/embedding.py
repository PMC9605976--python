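"""Developmental-trajectory embedding of morphometric cohorts.

Cohorts of 24-parameter egg-chamber records are standardized (wild type
alone, or a manipulated genotype pooled with its control), reduced by PCA
keeping the smallest number of components whose cumulative explained
variance exceeds 90%, and embedded with UMAP (n_neighbors = 15,
min_dist = 0.2).  Chambers are ordered along the developmental trajectory
by geodesic distance from the smallest-germline chamber on the k-NN graph
of the embedding, and genotype divergence from a control trajectory is
detected by a permutation-calibrated sliding-window scan over germline
area.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.sparse.csgraph import dijkstra
from sklearn.decomposition import PCA
from sklearn.neighbors import kneighbors_graph

from .morphometrics import PARAMETER_COLUMNS

__all__ = [
    "EmbeddingParams",
    "EmbeddingResult",
    "DivergenceResult",
    "standardize",
    "pca_select",
    "umap_embed",
    "embed_cohort",
    "trajectory_order",
    "divergence_point",
]


@dataclass(frozen=True)
class EmbeddingParams:
    n_neighbors: int = 15
    min_dist: float = 0.2
    seed: int = 0
    cumvar_threshold: float = 0.90


@dataclass
class EmbeddingResult:
    pc_scores: np.ndarray  # (n, k)
    cumvar: np.ndarray  # cumulative explained-variance fractions
    umap_xy: np.ndarray | None = None  # (n, 2)
    trajectory_order: np.ndarray | None = None  # permutation of row indices
    params: EmbeddingParams = field(default_factory=EmbeddingParams)
    dropped_columns: tuple[str, ...] = ()

    @property
    def n_components(self) -> int:
        return self.pc_scores.shape[1]


@dataclass
class DivergenceResult:
    diverged: bool
    area_at_divergence: float  # NaN when not diverged
    window_centers: np.ndarray
    observed: np.ndarray  # mean mutant distance per window
    null_quantile: np.ndarray  # permutation threshold per window
    in_critical_ci: bool | None = None


# ----------------------------------------------------------------------------
# Standardization and PCA
# ----------------------------------------------------------------------------


def _numeric_block(table: pd.DataFrame) -> pd.DataFrame:
    cols = [c for c in PARAMETER_COLUMNS if c in table.columns]
    if not cols:  # tolerate generic numeric tables
        cols = [c for c in table.columns if np.issubdtype(table[c].dtype, np.number)]
    return table[cols].astype(float)


def standardize(
    cohort: pd.DataFrame,
    control: pd.DataFrame | None = None,
    mode: str = "wt_alone",
) -> pd.DataFrame:
    """Column-wise z-scores of the 24-parameter block.

    ``mode='wt_alone'`` standardizes the cohort against its own moments;
    ``mode='pooled_with_control'`` computes the moments on the cohort pooled
    with its control (the convention for genetically manipulated cohorts).
    Zero-variance columns are dropped with a warning.
    """
    if len(cohort) < 2:
        raise ValueError("need at least 2 rows to standardize")
    block = _numeric_block(cohort)
    if mode == "wt_alone":
        ref = block
    elif mode == "pooled_with_control":
        if control is None:
            raise ValueError("pooled_with_control requires a control cohort")
        ref = pd.concat([_numeric_block(control), block], axis=0)
    else:
        raise ValueError(f"unknown standardization mode {mode!r}")
    mu = ref.mean(axis=0)
    sd = ref.std(axis=0, ddof=0)
    keep = sd > 1e-12
    if not keep.all():
        dropped = list(sd.index[~keep])
        warnings.warn(f"dropping zero-variance columns: {dropped}", stacklevel=2)
    z = (block.loc[:, keep] - mu[keep]) / sd[keep]
    return z


def pca_select(
    z: pd.DataFrame | np.ndarray, cumvar_threshold: float = 0.90
) -> EmbeddingResult:
    """PCA keeping the smallest k with cumulative variance > threshold."""
    if not 0.0 < cumvar_threshold < 1.0:
        raise ValueError("cumvar_threshold must lie in (0, 1)")
    X = np.asarray(z, dtype=float)
    pca = PCA()
    scores = pca.fit_transform(X)
    cumvar = np.cumsum(pca.explained_variance_ratio_)
    k = int(np.searchsorted(cumvar, cumvar_threshold) + 1)
    k = min(k, scores.shape[1])
    return EmbeddingResult(
        pc_scores=scores[:, :k],
        cumvar=cumvar,
        params=EmbeddingParams(cumvar_threshold=cumvar_threshold),
    )


# ----------------------------------------------------------------------------
# UMAP and trajectory ordering
# ----------------------------------------------------------------------------


def umap_embed(
    pc_scores: np.ndarray,
    params: EmbeddingParams | None = None,
    germline_area: np.ndarray | None = None,
) -> EmbeddingResult:
    """Seeded 2-D UMAP of PC scores, plus geodesic trajectory order.

    The trajectory order walks the k-NN graph of the embedding by geodesic
    distance from the chamber with the smallest germline area (or from row
    0 when areas are not given).
    """
    params = params or EmbeddingParams()
    X = np.asarray(pc_scores, dtype=float)
    if X.shape[0] < params.n_neighbors + 1:
        raise ValueError(
            f"need at least n_neighbors+1={params.n_neighbors + 1} rows, "
            f"got {X.shape[0]}"
        )
    import umap

    reducer = umap.UMAP(
        n_neighbors=params.n_neighbors,
        min_dist=params.min_dist,
        n_components=2,
        random_state=params.seed,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        xy = np.asarray(reducer.fit_transform(X), dtype=float)
    if not np.all(np.isfinite(xy)):
        raise RuntimeError("UMAP produced non-finite coordinates")
    order = trajectory_order(xy, germline_area, k=params.n_neighbors)
    pca_part = pca_select(X) if X.ndim == 2 else None
    return EmbeddingResult(
        pc_scores=X,
        cumvar=pca_part.cumvar if pca_part else np.array([]),
        umap_xy=xy,
        trajectory_order=order,
        params=params,
    )


def trajectory_order(
    xy: np.ndarray, germline_area: np.ndarray | None = None, k: int = 15
) -> np.ndarray:
    """Row order by geodesic k-NN-graph distance from the trajectory start."""
    xy = np.asarray(xy, dtype=float)
    n = xy.shape[0]
    start = 0 if germline_area is None else int(np.argmin(germline_area))
    G = kneighbors_graph(xy, n_neighbors=min(k, n - 1), mode="distance")
    d = dijkstra(G, directed=False, indices=start)
    # unreachable nodes (disconnected graph) sort after reachable ones,
    # by Euclidean distance from the start as a fallback
    far = ~np.isfinite(d)
    if far.any():
        eu = np.linalg.norm(xy - xy[start], axis=1)
        d = np.where(far, d[np.isfinite(d)].max() + eu, d)
    return np.argsort(d, kind="stable")


def embed_cohort(
    table: pd.DataFrame,
    control: pd.DataFrame | None = None,
    params: EmbeddingParams | None = None,
) -> EmbeddingResult:
    """standardize -> pca_select -> umap_embed for one cohort table."""
    params = params or EmbeddingParams()
    mode = "wt_alone" if control is None else "pooled_with_control"
    z = standardize(table, control, mode=mode)
    pcs = pca_select(z, params.cumvar_threshold)
    area = table["germline_area"].to_numpy() if "germline_area" in table else None
    res = umap_embed(pcs.pc_scores, params, germline_area=area)
    res.cumvar = pcs.cumvar
    return res


# ----------------------------------------------------------------------------
# Divergence detection
# ----------------------------------------------------------------------------


def divergence_point(
    control: pd.DataFrame,
    mutant: pd.DataFrame,
    critical_size: float | None = None,
    critical_ci: tuple[float, float] | None = None,
    params: EmbeddingParams | None = None,
    n_windows: int = 32,
    B: int = 200,
    alpha: float = 0.01,
    persistence: int = 2,
) -> DivergenceResult:
    """First germline area at which the mutant leaves the control trajectory.

    Both cohorts are pooled, standardized together and embedded; each
    mutant chamber's distance to the nearest control chamber in the
    embedding is scanned in overlapping area windows.  A window is flagged
    when the observed mean distance exceeds the (1 - alpha) quantile of
    ``B`` label permutations, and divergence is called at the first run of
    ``persistence`` consecutive flagged windows.
    """
    for name, tbl in (("control", control), ("mutant", mutant)):
        if "germline_area" not in tbl.columns:
            raise ValueError(f"{name} cohort lacks a germline_area column")
    a_c = control["germline_area"].to_numpy(float)
    a_m = mutant["germline_area"].to_numpy(float)
    if a_m.max() < a_c.min() or a_c.max() < a_m.min():
        raise ValueError("cohorts have non-overlapping germline-area ranges")

    params = params or EmbeddingParams()
    pooled = pd.concat([control, mutant], axis=0, ignore_index=True)
    z = standardize(pooled, mode="wt_alone")
    pcs = pca_select(z, params.cumvar_threshold)
    res = umap_embed(
        pcs.pc_scores, params, germline_area=pooled["germline_area"].to_numpy()
    )
    xy = res.umap_xy
    n_c = len(control)
    is_mut = np.zeros(len(pooled), dtype=bool)
    is_mut[n_c:] = True
    areas = pooled["germline_area"].to_numpy(float)

    def mean_nn_dist(mut_mask: np.ndarray, rows: np.ndarray) -> float:
        mut_rows = rows[mut_mask[rows]]
        ctl_rows = rows[~mut_mask[rows]]
        if mut_rows.size == 0 or ctl_rows.size < 3:
            return np.nan
        d = np.linalg.norm(
            xy[mut_rows][:, None, :] - xy[ctl_rows][None, :, :], axis=2
        )
        return float(d.min(axis=1).mean())

    lo = max(a_c.min(), a_m.min())
    hi = min(a_c.max(), a_m.max())
    edges = np.exp(np.linspace(np.log(lo), np.log(hi), n_windows + 1))
    centers, lowers, obs, thresh, pvals = [], [], [], [], []
    rng = np.random.default_rng(params.seed)
    for i in range(n_windows - 1):
        sel = (areas >= edges[i]) & (areas <= edges[i + 2])  # overlapping
        rows = np.flatnonzero(sel)
        o = mean_nn_dist(is_mut, rows)
        if np.isnan(o):
            continue
        null = []
        for _ in range(B):
            perm = is_mut.copy()
            perm[rows] = rng.permutation(perm[rows])
            v = mean_nn_dist(perm, rows)
            if not np.isnan(v):
                null.append(v)
        if len(null) < max(10, B // 2):
            continue
        null = np.asarray(null)
        centers.append(np.sqrt(edges[i] * edges[i + 2]))
        lowers.append(edges[i])
        obs.append(o)
        thresh.append(float(np.quantile(null, 1.0 - alpha)))
        pvals.append((np.sum(null >= o - 1e-12) + 1.0) / (null.size + 1.0))

    centers = np.asarray(centers)
    obs = np.asarray(obs)
    thresh = np.asarray(thresh)
    # permutation p-values tolerate ties between the observed statistic and
    # the null quantile in nearly label-deterministic windows
    alpha_eff = max(alpha, 2.0 / (B + 1.0))
    flagged = np.asarray(pvals) <= alpha_eff
    diverged = False
    area_div = float("nan")
    # call divergence at the first flagged window that is confirmed by a
    # second flag within the next two windows (one non-flagged gap allowed,
    # e.g. a label-degenerate window with a tied permutation null); report
    # the first window's lower edge, where the separation began
    for i in range(len(flagged)):
        if flagged[i] and (persistence < 2 or np.any(flagged[i + 1 : i + 3])):
            diverged = True
            area_div = float(lowers[i])
            break
    in_ci = None
    if critical_ci is not None and diverged:
        in_ci = bool(critical_ci[0] <= area_div <= critical_ci[1])
    elif critical_size is not None and diverged:
        in_ci = bool(abs(area_div - critical_size) / critical_size < 0.2)
    return DivergenceResult(
        diverged=diverged,
        area_at_divergence=area_div,
        window_centers=centers,
        observed=obs,
        null_quantile=thresh,
        in_critical_ci=in_ci,
    )
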