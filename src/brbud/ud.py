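"""Utilization-distribution rasters by location interpolation (MKDE).

The kernel estimator works out the time-integrated bridge density without
quadrature: each included track segment is divided into ``n_i = round(T_i /
tau)`` equal activity-time intervals, locations are interpolated along the
chord at those times, and every recorded or interpolated location receives a
circular Gaussian kernel whose bandwidth follows the total-variance schedule
(h_min at recorded fixes, a mid-segment maximum capped at h_max).  Constant
``tau`` makes the local density of interpolated points proportional to the
time spent per unit length, which is exactly the time weighting the bridge
formulation requires.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .bridge import VarianceParams, smoothing_parameter
from .raster import GridSpec, write_esri_ascii, read_esri_ascii

__all__ = [
    "InterpolationPlan",
    "UDRaster",
    "default_tau",
    "plan_interpolation",
    "compute_ud",
    "isopleth_mask",
    "isopleth_areas",
    "export_ud",
    "read_ud",
    "grid_for_plan",
]

logger = logging.getLogger(__name__)


@dataclass
class InterpolationPlan:
    """Interpolated locations and their kernel bandwidths."""

    points: np.ndarray  # (N_L, 2) metres
    h: np.ndarray       # (N_L,) bandwidths, metres
    tau: float          # interpolation time constant, minutes
    n_per_segment: pd.Series = field(repr=False, default=None)

    @property
    def n_locations(self) -> int:
        return len(self.points)


@dataclass
class UDRaster:
    """Gridded space-use density (1/m^2) at cell centres."""

    grid: GridSpec
    values: np.ndarray  # shape grid.shape, row 0 = bottom
    normalized: bool
    raw_mass: float  # sum * cell_area before renormalization

    @property
    def mass(self) -> float:
        return float(self.values.sum() * self.grid.cell_area)


def _round_half_away(x: np.ndarray) -> np.ndarray:
    return np.floor(np.abs(x) + 0.5) * np.sign(x)


def default_tau(segments: pd.DataFrame, params: VarianceParams,
                cap: int = 1000) -> float:
    """Largest tau honouring the spacing constraint, with n_i capped.

    The constraint ``h_min > 0.5 * tau * L_i / T_i`` keeps interpolated
    points closer together than the kernel bandwidth; the cap bounds cost on
    very long active segments.
    """
    inc = segments[segments["included"]] if "included" in segments else segments
    sel = (inc["L"].to_numpy() > 0) & (inc["T"].to_numpy() > 0)
    if not sel.any():
        return params.T_max / 10.0
    L, T = inc["L"].to_numpy()[sel], inc["T"].to_numpy()[sel]
    tau = float(np.min(2.0 * params.h_min * T / L)) * 0.999
    tau = max(tau, float(T.max()) / cap)
    return tau


def plan_interpolation(segments: pd.DataFrame, tau: float,
                       params: VarianceParams) -> InterpolationPlan:
    """Interpolated locations with bandwidths for all included segments.

    Each included segment contributes its start fix plus n_i - 1 interior
    locations; the end fix of each maximal run of contiguous included
    segments is appended once, so shared endpoints are never double-counted.
    Recorded fixes belonging only to excluded segments still enter once with
    bandwidth h_min -- when every segment is excluded the plan degenerates
    to a classical fixed-bandwidth location KDE.
    """
    if not tau > 0:
        raise ValueError("tau must be > 0")
    segments = segments.reset_index(drop=True)
    included = segments["included"].to_numpy() if "included" in segments \
        else np.ones(len(segments), dtype=bool)
    null_d = segments["null_d"].to_numpy() if "null_d" in segments \
        else np.zeros(len(segments), dtype=bool)

    # spacing constraint checked over all included moving segments
    inc = segments[included]
    moving = (inc["L"].to_numpy() > 0) & (inc["T"].to_numpy() > 0)
    if moving.any():
        ratio = 0.5 * tau * inc["L"].to_numpy()[moving] / inc["T"].to_numpy()[moving]
        worst = float(ratio.max())
        if worst >= params.h_min:
            raise ValueError(
                f"interpolated-point spacing {2 * worst:.1f} m exceeds twice "
                f"h_min = {params.h_min:g} m for some segment; choose a "
                "smaller tau or a larger sigma_min"
            )

    pts: list[np.ndarray] = []
    hs: list[np.ndarray] = []
    n_per = {}
    covered: set[tuple] = set()  # (id, t) of fixes already contributed
    n = len(segments)
    ids = segments["id"].to_numpy()
    t0 = segments["t0"].to_numpy()
    t1 = segments["t1"].to_numpy()
    for k in range(n):
        if not included[k]:
            continue
        row = segments.iloc[k]
        T_i = float(row["T"])
        n_i = max(1, int(_round_half_away(np.asarray(T_i / tau))))
        n_per[k] = n_i
        m = np.arange(n_i)
        z0 = np.array([row["x0"], row["y0"]], dtype=float)
        z1 = np.array([row["x1"], row["y1"]], dtype=float)
        pts.append(z0 + (z1 - z0) * (m[:, None] / n_i))
        if null_d[k] or T_i <= 0:
            hs.append(np.full(n_i, params.h_min))
        else:
            hs.append(np.asarray(smoothing_parameter(m, n_i, T_i, params),
                                 dtype=float).reshape(n_i))
        covered.add((row["id"], float(row["t0"])))
        # close the run if the next segment is not a contiguous included one
        last = (k + 1 >= n or not included[k + 1] or ids[k + 1] != ids[k]
                or t0[k + 1] != t1[k])
        if last:
            pts.append(z1[None, :])
            hs.append(np.array([params.h_min]))
        covered.add((row["id"], float(row["t1"])))

    # recorded fixes only touched by excluded segments: plain h_min kernels
    seen: set[tuple] = set()
    for k in range(n):
        row = segments.iloc[k]
        for which in ("0", "1"):
            key = (row["id"], float(row[f"t{which}"]))
            if key in covered or key in seen:
                continue
            seen.add(key)
            pts.append(np.array([[row[f"x{which}"], row[f"y{which}"]]],
                                dtype=float))
            hs.append(np.array([params.h_min]))

    if not pts:
        raise ValueError("no segments supplied")
    points = np.concatenate(pts, axis=0)
    h = np.concatenate(hs)
    logger.info("interpolation plan: %d locations (tau = %.3g min)",
                len(points), tau)
    return InterpolationPlan(points, h, tau,
                             pd.Series(n_per, name="n_i", dtype=int))


def grid_for_plan(plan: InterpolationPlan, cell: float,
                  params: VarianceParams, margin_factor: float = 4.0
                  ) -> GridSpec:
    """Grid covering the plan's locations with a margin of 4 h_max."""
    x, y = plan.points[:, 0], plan.points[:, 1]
    return GridSpec.from_bounds(float(x.min()), float(x.max()),
                                float(y.min()), float(y.max()),
                                cell, margin=margin_factor * params.h_max)


def compute_ud(plan: InterpolationPlan, grid: GridSpec,
               truncate: float = 4.0) -> UDRaster:
    """Sum the per-location Gaussian kernels on the grid and normalize.

    Kernels are truncated at ``truncate`` bandwidths (relative mass loss
    below 1e-4 at the default 4); the raster is renormalized to unit mass so
    the truncation and any off-grid tail never bias isopleths.
    """
    if plan.n_locations == 0:
        raise ValueError("empty interpolation plan")
    values = np.zeros(grid.shape, dtype=float)
    xc, yc = grid.x_centers, grid.y_centers
    for (px, py), h in zip(plan.points, plan.h):
        r = truncate * h
        i0 = max(0, int(np.floor((px - r - grid.x_min) / grid.cell)))
        i1 = min(grid.n_cols, int(np.ceil((px + r - grid.x_min) / grid.cell)) + 1)
        j0 = max(0, int(np.floor((py - r - grid.y_min) / grid.cell)))
        j1 = min(grid.n_rows, int(np.ceil((py + r - grid.y_min) / grid.cell)) + 1)
        if i0 >= i1 or j0 >= j1:
            continue
        dx2 = (xc[i0:i1] - px) ** 2
        dy2 = (yc[j0:j1] - py) ** 2
        d2 = dy2[:, None] + dx2[None, :]
        block = np.exp(-d2 / (2.0 * h * h))
        block[d2 > r * r] = 0.0
        values[j0:j1, i0:i1] += block / (2.0 * np.pi * h * h)
    values /= plan.n_locations
    raw_mass = float(values.sum() * grid.cell_area)
    if raw_mass <= 0:
        raise ValueError("no kernel mass falls on the grid")
    if abs(raw_mass - 1.0) > 0.05:
        logger.warning("%.1f%% of kernel mass falls off-grid; consider a "
                       "larger margin", 100 * abs(1 - raw_mass))
    values /= raw_mass
    return UDRaster(grid, values, normalized=True, raw_mass=raw_mass)


def isopleth_mask(ud: UDRaster, level: float) -> np.ndarray:
    """Boolean mask of cells inside the given cumulative-frequency isopleth.

    Cells are ranked by density (ties broken by row-major index); a cell is
    inside when the cumulative mass up to and including it does not exceed
    level/100.
    """
    if not 0 < level <= 100:
        raise ValueError("isopleth level must lie in (0, 100]")
    if not ud.normalized:
        raise ValueError("UD must be normalized")
    flat = ud.values.ravel()
    order = np.lexsort((np.arange(flat.size), -flat))
    cum = np.cumsum(flat[order]) * ud.grid.cell_area
    inside_sorted = cum <= level / 100.0 * (1.0 + 1e-9) + 1e-12
    mask = np.zeros(flat.size, dtype=bool)
    mask[order[inside_sorted]] = True
    return mask.reshape(ud.values.shape)


def isopleth_areas(ud: UDRaster, levels) -> dict[float, float]:
    """Area (m^2) enclosed by each cumulative-frequency isopleth level."""
    return {float(p): float(isopleth_mask(ud, p).sum() * ud.grid.cell_area)
            for p in levels}


def export_ud(ud: UDRaster, path, format: str = "esri_ascii") -> None:
    """Write the UD raster as an ESRI ASCII grid or a long-format CSV."""
    if not ud.normalized:
        raise ValueError("UD must be normalized before export")
    if format == "esri_ascii":
        write_esri_ascii(ud.grid, ud.values, path, nodata=-9999)
    elif format == "csv":
        xx, yy = np.meshgrid(ud.grid.x_centers, ud.grid.y_centers)
        pd.DataFrame({"x": xx.ravel(), "y": yy.ravel(),
                      "density": ud.values.ravel()}).to_csv(path, index=False)
    else:
        raise ValueError(f"unsupported export format {format!r}")


def read_ud(path) -> UDRaster:
    """Read a UD raster previously exported as ESRI ASCII."""
    grid, values, _ = read_esri_ascii(path)
    mass = float(values.sum() * grid.cell_area)
    return UDRaster(grid, values, normalized=abs(mass - 1.0) < 1e-3,
                    raw_mass=mass)
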