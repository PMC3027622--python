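"""Simplified (isotropic) biased-random-bridge mathematics.

A biased random bridge (BRB) is an advective-diffusive random walk conditioned
on both endpoints of a track segment.  In the simplified (isotropic) form the
pinned density at intermediate activity time ``t`` is a circular bivariate
Gaussian centred on the point that slides at constant speed along the chord
between the two relocations, with a movement variance that vanishes at the
endpoints and peaks at mid-time -- formally identical to a Brownian bridge, so
the drift never needs to be known to evaluate it.

The module provides the movement- and total-variance models, the pinned
bridge density, its time integral by quadrature (the brute-force oracle for
the kernel estimator in :mod:`brbud.ud`), and the discrete smoothing schedule
that maps interpolated locations to kernel bandwidths.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "VarianceParams",
    "BridgeSpec",
    "movement_variance",
    "total_variance",
    "bridge_density",
    "integrated_bridge_density",
    "smoothing_parameter",
]

#: variance-model modes: relocation variance enters with constant weight
#: ("constant_weight") or progressively merges with the movement variance
#: ("merging").
MODES = ("constant_weight", "merging")

_MODE_ALIASES = {
    "constant_weight": "constant_weight",
    "merging": "merging",
    "4a": "constant_weight",
    "4b": "merging",
}


@dataclass(frozen=True)
class VarianceParams:
    """Variance model of a simplified BRB.

    Parameters
    ----------
    sigma_min : float
        Minimum relocation standard deviation (m).  Reflects habitat grain
        and the positional uncertainty of the individual relative to the
        recorded fix; it is the bandwidth attached to every recorded
        location (``h_min``).
    D : float
        Diffusion coefficient (m^2/min).
    T_max : float
        Upper recording-interval threshold (min) warranting constant
        within-bridge drift; segments longer in time are excluded upstream.
    mode : str
        "constant_weight" (alias "4a") or "merging" (alias "4b").
    """

    sigma_min: float
    D: float
    T_max: float
    mode: str = "constant_weight"

    def __post_init__(self) -> None:
        object.__setattr__(self, "mode", _MODE_ALIASES.get(self.mode, self.mode))
        if self.mode not in MODES:
            raise ValueError(f"unknown variance mode {self.mode!r}")
        if not self.sigma_min > 0:
            raise ValueError("sigma_min must be > 0")
        if self.D < 0:
            raise ValueError("D must be >= 0")
        if not self.T_max > 0:
            raise ValueError("T_max must be > 0")
        if self.mode == "merging" and self.D <= 2.0 * self.sigma_min**2 / self.T_max:
            raise ValueError(
                "merging mode requires D > 2*sigma_min^2/T_max "
                f"(= {2.0 * self.sigma_min**2 / self.T_max:g} m^2/min)"
            )

    @property
    def beta_tmax(self) -> float:
        """Upper limit of the movement standard deviation, (D*T_max/2)^0.5 (m)."""
        return float(np.sqrt(self.D * self.T_max / 2.0))

    @property
    def h_min(self) -> float:
        """Minimum smoothing parameter (m); equals sigma_min."""
        return self.sigma_min

    @property
    def h_max(self) -> float:
        """Maximum smoothing parameter (m), reached at the centre of a
        fully-active segment lasting T_max."""
        if self.mode == "constant_weight":
            return float(np.sqrt(self.sigma_min**2 + self.D * self.T_max / 2.0))
        return self.beta_tmax


@dataclass(frozen=True)
class BridgeSpec:
    """One bridge: two successive relocations and the activity time between."""

    z0: tuple[float, float]
    zT: tuple[float, float]
    T: float

    def __post_init__(self) -> None:
        if not self.T > 0:
            raise ValueError("bridge duration T must be > 0")

    def mu(self, t) -> np.ndarray:
        """Expected location at activity time t: slides along the chord."""
        t = np.asarray(t, dtype=float)
        z0 = np.asarray(self.z0, dtype=float)
        zT = np.asarray(self.zT, dtype=float)
        frac = (t / self.T)[..., None] if t.ndim else t / self.T
        return z0 + (zT - z0) * frac


def movement_variance(t, T: float, D: float):
    """Per-axis movement variance 2*D*t*(1 - t/T) of a pinned bridge (m^2).

    Zero at both endpoints, maximal (= D*T/2) at t = T/2.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0) or np.any(t > T):
        raise ValueError("t must lie in [0, T]")
    out = 2.0 * D * t * (1.0 - t / T)
    return float(out) if out.ndim == 0 else out


def total_variance(t, T: float, params: VarianceParams):
    """Per-axis total variance (m^2): relocation + movement components.

    constant_weight mode adds sigma_min^2 as a constant floor,
        sigma_min^2 + 2*D*t*(1 - t/T);
    merging mode blends the floor into the movement component,
        sigma_min^2*(1 - w) + beta_Tmax^2*w  with  w = 4*t*(1 - t/T)/T_max.
    Both equal sigma_min^2 at t = 0 and t = T.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0) or np.any(t > T):
        raise ValueError("t must lie in [0, T]")
    if T > params.T_max:
        raise ValueError("T must not exceed T_max")
    s2 = params.sigma_min**2
    if params.mode == "constant_weight":
        out = s2 + movement_variance(t, T, params.D)
    else:
        w = 4.0 * t * (1.0 - t / T) / params.T_max
        out = s2 * (1.0 - w) + params.beta_tmax**2 * w
    out = np.asarray(out)
    return float(out) if out.ndim == 0 else out


def bridge_density(z, t: float, spec: BridgeSpec, variance: float):
    """Pinned bridge density at location(s) ``z`` and activity time ``t``.

    A circular bivariate Gaussian centred on ``spec.mu(t)`` with the given
    per-axis variance; independent of the drift. ``z`` has shape (..., 2);
    returns density in 1/m^2 with shape ``z.shape[:-1]``.
    """
    if not variance > 0:
        raise ValueError("variance must be > 0")
    if not 0 < t < spec.T:
        raise ValueError("t must lie strictly inside (0, T)")
    z = np.asarray(z, dtype=float)
    mu = spec.mu(np.asarray(t))
    d2 = np.sum((z - mu) ** 2, axis=-1)
    out = np.exp(-d2 / (2.0 * variance)) / (2.0 * np.pi * variance)
    return float(out) if out.ndim == 0 else out


def integrated_bridge_density(z, spec: BridgeSpec, params: VarianceParams,
                              n_quad: int = 64):
    """Time-averaged bridge density (1/T) * integral_0^T f_B(z, t) dt.

    Composite midpoint quadrature with ``n_quad`` nodes; the total variance
    keeps the integrand finite at the endpoints (floor sigma_min^2).  Serves
    as the brute-force oracle for the interpolation-based kernel estimator.
    """
    if n_quad < 16:
        raise ValueError("n_quad must be >= 16")
    if spec.T > params.T_max:
        raise ValueError("bridge duration exceeds T_max")
    z = np.asarray(z, dtype=float)
    nodes = (np.arange(n_quad) + 0.5) * spec.T / n_quad
    acc = np.zeros(z.shape[:-1], dtype=float)
    for t in nodes:
        var = total_variance(t, spec.T, params)
        acc += bridge_density(z, float(t), spec, var)
    acc /= n_quad
    return float(acc) if acc.ndim == 0 else acc


def smoothing_parameter(m, n_i: int, T_i: float, params: VarianceParams):
    """Kernel bandwidth h (m) for the m-th interpolated location of a segment.

    The discrete-time expression of the total standard deviation:
    ``h = sqrt(total_variance(m*T_i/n_i, T_i))``.  Recorded locations
    (m = 0 or m = n_i) get h_min; the mid-segment maximum grows with T_i and
    reaches h_max when T_i = T_max.
    """
    if n_i < 1:
        raise ValueError("n_i must be >= 1")
    m = np.asarray(m)
    if np.any(m < 0) or np.any(m > n_i):
        raise ValueError("m must lie in [0, n_i]")
    # guard the t = T endpoint against floating-point overshoot
    t = np.clip(m.astype(float) * T_i / n_i, 0.0, T_i)
    out = np.sqrt(total_variance(t, T_i, params)) if T_i > 0 else np.full(
        np.shape(m), params.h_min, dtype=float
    )
    out = np.asarray(out)
    return float(out) if out.ndim == 0 else out
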