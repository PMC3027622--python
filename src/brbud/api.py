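"""Scikit-learn style estimator surface.

`DiffusionEstimator` and `DriftSpeedEstimator` are parameter estimators
(fit on a segments frame); `BRBDensity` is the full movement-based density
estimator: fit on a fixes frame, fitted attributes expose the segments,
interpolation plan and UD raster, and `score_samples` evaluates the fitted
kernel mixture at arbitrary planar points.  All three follow the
get_params/set_params contract, so they compose with sklearn tooling
(cloning, grid search over e.g. T_max or tau).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from . import estimators as est
from . import trajectory as traj
from .bridge import VarianceParams
from .raster import GridSpec, HabitatMap
from .ud import (compute_ud, default_tau, grid_for_plan, isopleth_areas,
                 isopleth_mask, plan_interpolation)

__all__ = ["DiffusionEstimator", "DriftSpeedEstimator", "BRBDensity"]


class DiffusionEstimator(BaseEstimator):
    """Diffusion coefficient from couples of consecutive track segments.

    Parameters
    ----------
    T_max : float
        Maximum summed recording time of a couple (min).
    aggregation : {"mean", "pooled"}
        Mean of per-couple unbiased estimates (default) or pooled ratio.
    sample_step : float or None
        Chord sampling step (m) used to decide whether a segment is fully
        inside one habitat type; defaults to half the habitat cell size.

    Attributes
    ----------
    D_ : float
        Global diffusion coefficient (m^2/min).
    n_couples_ : int
        Number of retained couples.
    couples_ : DataFrame
        Per-couple diagnostics (delta^2, activity times, per-couple D).
    beta_ : float
        Movement-variance upper bound sqrt(D * T_max / 2) (m).
    per_habitat_ : dict[int, DiffusionEstimate]
        Present when a habitat map was supplied to :meth:`fit`.
    """

    def __init__(self, T_max: float = 180.0, aggregation: str = "mean",
                 sample_step: float | None = None):
        self.T_max = T_max
        self.aggregation = aggregation
        self.sample_step = sample_step

    def fit(self, X: pd.DataFrame, y=None, habitat: HabitatMap | None = None):
        couples = est.diffusion_couples(X, self.T_max)
        res = est.estimate_d(couples, self.aggregation)
        self.D_ = res.D_hat
        self.n_couples_ = res.n_couples
        self.couples_ = res.couples
        self.beta_ = res.beta(self.T_max)
        if habitat is not None:
            step = self.sample_step or habitat.grid.cell / 2.0
            self.per_habitat_ = est.estimate_d_by_habitat(
                X, habitat, self.T_max, step, self.aggregation)
        return self


class DriftSpeedEstimator(BaseEstimator):
    """Habitat-specific squared drift speeds from single segments.

    ``D`` is the diffusion coefficient used in E[L^2] = v^2 T^2 + 4 D T:
    a scalar, a ``{code: D_H}`` mapping, or None to estimate the global D
    from the same segments at fit time.
    """

    def __init__(self, D=None, T_max: float = 180.0,
                 aggregation: str = "mean", sample_step: float | None = None):
        self.D = D
        self.T_max = T_max
        self.aggregation = aggregation
        self.sample_step = sample_step

    def fit(self, X: pd.DataFrame, y=None, habitat: HabitatMap | None = None):
        if habitat is None:
            raise ValueError("drift speeds are habitat-specific; a habitat "
                             "map is required")
        d = self.D
        if d is None:
            d = est.estimate_d(est.diffusion_couples(X, self.T_max),
                               self.aggregation).D_hat
        step = self.sample_step or habitat.grid.cell / 2.0
        self.estimates_ = est.estimate_drift_speeds(X, habitat, d, step,
                                                    self.aggregation)
        self.v_sq_ = {e.habitat_code: e.v_sq for e in self.estimates_}
        self.v_ = {e.habitat_code: e.v for e in self.estimates_}
        return self


class BRBDensity(BaseEstimator):
    """Movement-based utilization-distribution estimator (BRB via MKDE).

    Parameters
    ----------
    sigma_min : float
        Minimum relocation standard deviation / minimum bandwidth (m).
    D : float or "estimate"
        Diffusion coefficient (m^2/min), or "estimate" to fit it from the
        track's own relocation triplets.
    T_max : float
        Maximum recording interval entering UD computation (min).
    tau : float or None
        Interpolation time constant (min); None picks the largest value
        honouring the spacing constraint.
    variance_mode : {"constant_weight", "merging"} (aliases "4a"/"4b")
    L_min : float
        Minimum segment length (m); shorter active segments are dropped or,
        with ``immobile_active_mode="keep_null_D"``, kept with a null
        diffusion coefficient.
    global_mode : bool
        Spread resting time around fixes (global rather than active-time UD).
    cell_size : float or None
        Grid resolution (m); defaults to sigma_min / 2.
    margin_factor : float
        Grid margin in multiples of h_max.

    Attributes
    ----------
    segments_ : DataFrame;  params_ : VarianceParams;  D_ : float
    plan_ : InterpolationPlan;  grid_ : GridSpec;  ud_ : UDRaster
    lkde_degenerate_ : bool
        True when no segment passed the T_max filter, in which case the UD
        is a fixed-bandwidth (h_min) KDE of the recorded locations.
    """

    def __init__(self, sigma_min: float = 100.0, D="estimate",
                 T_max: float = 180.0, tau: float | None = None,
                 variance_mode: str = "constant_weight", L_min: float = 0.0,
                 immobile_active_mode: str = "drop", global_mode: bool = False,
                 cell_size: float | None = None, margin_factor: float = 4.0,
                 grid: GridSpec | None = None, truncate: float = 4.0):
        self.sigma_min = sigma_min
        self.D = D
        self.T_max = T_max
        self.tau = tau
        self.variance_mode = variance_mode
        self.L_min = L_min
        self.immobile_active_mode = immobile_active_mode
        self.global_mode = global_mode
        self.cell_size = cell_size
        self.margin_factor = margin_factor
        self.grid = grid
        self.truncate = truncate

    def fit(self, X: pd.DataFrame, y=None):
        """Fit on a fixes frame (columns id, t, x, y, p)."""
        segments = traj.build_segments(X)
        if self.global_mode:
            segments = traj.apply_global_mode(segments)
        segments = traj.filter_segments(segments, self.T_max, self.L_min,
                                        self.immobile_active_mode)
        if self.D == "estimate":
            couples = est.diffusion_couples(segments, self.T_max)
            self.D_ = est.estimate_d(couples).D_hat
            if not np.isfinite(self.D_):
                raise ValueError("could not estimate D from this track "
                                 "(no retained couples); pass D explicitly")
        else:
            self.D_ = float(self.D)
        self.params_ = VarianceParams(self.sigma_min, self.D_, self.T_max,
                                      self.variance_mode)
        self.segments_ = segments
        self.lkde_degenerate_ = not bool(segments["included"].any())
        self.tau_ = self.tau if self.tau is not None else \
            default_tau(segments, self.params_)
        self.plan_ = plan_interpolation(segments, self.tau_, self.params_)
        cell = self.cell_size if self.cell_size is not None else \
            self.sigma_min / 2.0
        self.grid_ = self.grid if self.grid is not None else \
            grid_for_plan(self.plan_, cell, self.params_, self.margin_factor)
        self.ud_ = compute_ud(self.plan_, self.grid_, self.truncate)
        return self

    def score_samples(self, X) -> np.ndarray:
        """Log-density of the fitted kernel mixture at points X (n, 2)."""
        check_is_fitted(self, "plan_")
        X = np.asarray(X, dtype=float)
        pts, h = self.plan_.points, self.plan_.h
        d2 = ((X[:, None, :] - pts[None, :, :]) ** 2).sum(-1)
        dens = np.exp(-d2 / (2 * h**2)) / (2 * np.pi * h**2)
        return np.log(dens.mean(axis=1))

    def isopleth(self, level: float = 95.0) -> np.ndarray:
        """Boolean cell mask of the given cumulative-frequency isopleth."""
        check_is_fitted(self, "ud_")
        return isopleth_mask(self.ud_, level)

    def isopleth_areas(self, levels=(50.0, 95.0)) -> dict[float, float]:
        check_is_fitted(self, "ud_")
        return isopleth_areas(self.ud_, levels)
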