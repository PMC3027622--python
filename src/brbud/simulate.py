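"""Synthetic movement tracks: biased / correlated random walks, GPS-like
subsampling with activity, and endpoint-conditioned bridge ensembles.

Walks are discrete-step with constant step length ``s * dt`` and headings
drawn from a von Mises distribution; its concentration kappa is solved from
the mean cosine ``c = E[cos(theta - phi)] = I1(kappa)/I0(kappa)``, the only
angular parameter the bridge theory uses.  A biased walk (brw) draws
absolute headings around the preferred direction phi and drifts at speed
``v = s*c``; a correlated walk (crw) draws turning angles around zero; a
biased-correlated walk (bcrw) steers around a weighted compromise between
the previous heading and phi.  With c = 0 every type degrades to Brownian
motion with diffusion coefficient ``D = s^2*dt/4``; more generally the
isotropically equivalent coefficient of a brw is ``D = s^2*dt*(1-c^2)/4``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import i0e, i1e

from .raster import HabitatMap

__all__ = [
    "WalkParams",
    "BridgeEnsemble",
    "kappa_from_concentration",
    "diffusion_coefficient",
    "simulate_walk",
    "simulate_paths",
    "gps_subsample",
    "bridge_ensemble",
]

logger = logging.getLogger(__name__)

WALK_TYPES = ("brownian", "brw", "crw", "bcrw")


@dataclass(frozen=True)
class WalkParams:
    """Parameters of a discrete-step random walk."""

    step_dt: float = 1.0       # step duration, min
    speed: float = 10.0        # m/min; step length = speed * step_dt
    phi: float = 0.0           # preferred absolute direction, rad
    c: float = 0.0             # angular concentration, mean cosine in [0, 1)
    kind: str = "brownian"
    bias_weight: float = 0.5   # bcrw only: weight of phi vs previous heading
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in WALK_TYPES:
            raise ValueError(f"unknown walk type {self.kind!r}")
        if not 0.0 <= self.c < 1.0:
            raise ValueError("concentration c must lie in [0, 1)")
        if not self.step_dt > 0 or self.speed < 0:
            raise ValueError("step_dt must be > 0 and speed >= 0")
        if not 0.0 <= self.bias_weight <= 1.0:
            raise ValueError("bias_weight must lie in [0, 1]")

    @property
    def drift_speed(self) -> float:
        """Drift speed v = s*c of a biased walk (m/min)."""
        return self.speed * self.c if self.kind == "brw" else float("nan")


def kappa_from_concentration(c: float) -> float:
    """Von Mises concentration kappa with mean cosine c = I1(k)/I0(k)."""
    if not 0.0 <= c < 1.0:
        raise ValueError("c must lie in [0, 1)")
    if c == 0.0:
        return 0.0
    hi = max(10.0, 2.0 / (1.0 - c))  # asymptotically c ~ 1 - 1/(2k)
    return float(brentq(lambda k: i1e(k) / i0e(k) - c, 1e-12, hi, xtol=1e-12))


def diffusion_coefficient(params: WalkParams) -> float:
    """Isotropically equivalent diffusion coefficient (m^2/min).

    For a constant-step walk with independent headings of mean cosine c:
    E[L^2] over n steps is v^2*T^2 + n*(s*dt)^2*(1 - c^2), hence
    D = s^2*dt*(1 - c^2)/4 (s^2*dt/4 for Brownian motion).
    """
    c = params.c if params.kind in ("brw", "brownian") else 0.0
    if params.kind == "brownian":
        c = 0.0
    return params.speed**2 * params.step_dt * (1.0 - c**2) / 4.0


def _headings(params: WalkParams, n_steps: int, n_paths: int,
              rng: np.random.Generator) -> np.ndarray:
    """Absolute headings, shape (n_paths, n_steps)."""
    kappa = kappa_from_concentration(params.c if params.kind != "brownian"
                                     else 0.0)
    if params.kind == "brownian" or kappa == 0.0:
        return rng.uniform(-np.pi, np.pi, size=(n_paths, n_steps))
    if params.kind == "brw":
        return rng.vonmises(params.phi, kappa, size=(n_paths, n_steps))
    if params.kind == "crw":
        turns = rng.vonmises(0.0, kappa, size=(n_paths, n_steps))
        start = rng.uniform(-np.pi, np.pi, size=(n_paths, 1))
        return start + np.cumsum(turns, axis=1)
    # bcrw: sequential compromise heading, cannot be vectorised over steps
    w = params.bias_weight
    out = np.empty((n_paths, n_steps))
    prev = rng.uniform(-np.pi, np.pi, size=n_paths)
    for k in range(n_steps):
        mu = np.arctan2(w * np.sin(params.phi) + (1 - w) * np.sin(prev),
                        w * np.cos(params.phi) + (1 - w) * np.cos(prev))
        prev = mu + rng.vonmises(0.0, kappa, size=n_paths)
        out[:, k] = prev
    return out


def simulate_paths(params: WalkParams, n_steps: int, n_paths: int,
                   rng: np.random.Generator | None = None,
                   start=(0.0, 0.0)) -> np.ndarray:
    """Positions of ``n_paths`` independent walks, shape (n_paths, n_steps+1, 2)."""
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    rng = np.random.default_rng(params.seed) if rng is None else rng
    theta = _headings(params, n_steps, n_paths, rng)
    step = params.speed * params.step_dt
    dxy = np.stack([step * np.cos(theta), step * np.sin(theta)], axis=-1)
    pos = np.empty((n_paths, n_steps + 1, 2))
    pos[:, 0] = np.asarray(start, dtype=float)
    pos[:, 1:] = pos[:, :1] + np.cumsum(dxy, axis=1)
    return pos


def simulate_walk(params: WalkParams, n_steps: int, start=(0.0, 0.0),
                  habitat: HabitatMap | None = None,
                  overrides: dict[int, tuple[float, float]] | None = None,
                  animal_id: str = "a1") -> pd.DataFrame:
    """One walk as a fixes frame (t in minutes, x/y in metres, p = 1).

    With a habitat map and ``overrides = {code: (speed, c)}``, the step
    parameters switch to the override of the habitat at the current
    position, which makes habitat-specific diffusion and drift recoverable
    downstream.
    """
    rng = np.random.default_rng(params.seed)
    if habitat is None or not overrides:
        pos = simulate_paths(params, n_steps, 1, rng, start)[0]
    else:
        kappa_cache = {None: kappa_from_concentration(
            params.c if params.kind != "brownian" else 0.0)}
        pos = np.empty((n_steps + 1, 2))
        pos[0] = start
        prev = rng.uniform(-np.pi, np.pi)
        for k in range(n_steps):
            code = habitat.code_at(pos[k, 0], pos[k, 1])
            s, c = overrides.get(code, (params.speed, params.c))
            if c not in kappa_cache:
                kappa_cache[c] = kappa_from_concentration(c)
            kappa = kappa_cache[c] if params.kind != "brownian" else 0.0
            if params.kind == "brw" and kappa > 0:
                theta = rng.vonmises(params.phi, kappa)
            elif params.kind == "crw" and kappa > 0:
                theta = prev + rng.vonmises(0.0, kappa)
            elif params.kind == "bcrw" and kappa > 0:
                w = params.bias_weight
                mu = np.arctan2(w * np.sin(params.phi) + (1 - w) * np.sin(prev),
                                w * np.cos(params.phi) + (1 - w) * np.cos(prev))
                theta = mu + rng.vonmises(0.0, kappa)
            else:
                theta = rng.uniform(-np.pi, np.pi)
            prev = theta
            step = s * params.step_dt
            pos[k + 1] = pos[k] + (step * np.cos(theta), step * np.sin(theta))
    t = np.arange(n_steps + 1) * params.step_dt
    return pd.DataFrame({"id": animal_id, "t": t, "x": pos[:, 0],
                         "y": pos[:, 1], "p": 1.0})


def _interval_activity(n_intervals: int, activity) -> np.ndarray:
    """Per-recording-interval activity proportions from an activity model."""
    if np.isscalar(activity):
        p = float(activity)
        if not 0.0 <= p <= 1.0:
            raise ValueError("constant activity must lie in [0, 1]")
        return np.full(n_intervals, p)
    tag, n_active, n_rest = activity
    if tag != "blocks" or n_active < 1 or n_rest < 1:
        raise ValueError("block activity model is ('blocks', n_active, n_rest)")
    cycle = np.r_[np.ones(int(n_active)), np.zeros(int(n_rest))]
    return np.tile(cycle, n_intervals // len(cycle) + 1)[:n_intervals]


def gps_subsample(fixes: pd.DataFrame, T_R: float, activity=1.0,
                  dropout: float = 0.0,
                  rng: np.random.Generator | None = None,
                  seed: int = 0) -> pd.DataFrame:
    """Emulate a GPS collar: keep one fix per T_R, attach activity, drop fixes.

    ``activity`` is either a constant proportion or ``("blocks", n_active,
    n_rest)`` alternating fully active and fully resting recording
    intervals.  Each interior retained fix is then lost independently with
    probability ``dropout``, creating doubled (or longer) recording
    intervals; the activity proportion of a merged interval is the
    time-weighted mean of the merged ones.
    """
    rng = np.random.default_rng(seed) if rng is None else rng
    t = fixes["t"].to_numpy()
    dt = np.diff(t)
    if len(dt) == 0 or not np.allclose(dt, dt[0]):
        raise ValueError("fixes must be regularly spaced in time")
    every = T_R / dt[0]
    if abs(every - round(every)) > 1e-9 or round(every) < 1:
        raise ValueError("T_R must be a multiple of the step duration")
    every = int(round(every))
    sub = fixes.iloc[::every].reset_index(drop=True)
    n_int = len(sub) - 1
    if n_int < 1:
        raise ValueError("track too short for this T_R")
    p = _interval_activity(n_int, activity)
    keep = np.ones(len(sub), dtype=bool)
    if dropout > 0:
        keep[1:-1] = rng.random(len(sub) - 2) >= dropout
    out_rows = []
    first = sub.iloc[0]
    out_rows.append((first["id"], float(first["t"]), float(first["x"]),
                     float(first["y"]), 1.0))
    acc_p, acc_t = 0.0, 0.0
    for j in range(n_int):
        acc_p += p[j] * T_R
        acc_t += T_R
        if keep[j + 1]:
            row = sub.iloc[j + 1]
            out_rows.append((row["id"], float(row["t"]), float(row["x"]),
                             float(row["y"]), acc_p / acc_t))
            acc_p, acc_t = 0.0, 0.0
    return pd.DataFrame(out_rows, columns=["id", "t", "x", "y", "p"])


@dataclass
class BridgeEnsemble:
    """Endpoint-conditioned walk ensemble and its deviation profile."""

    t: np.ndarray            # interior step times (min)
    delta_sq: np.ndarray     # mean squared deviation from the chord point
    n_accepted: int
    n_tried: int
    T: float
    tol: float

    @property
    def acceptance_rate(self) -> float:
        return self.n_accepted / self.n_tried if self.n_tried else 0.0

    @property
    def t_peak(self) -> float:
        """Time at which the mean squared deviation is maximal."""
        return float(self.t[int(np.argmax(self.delta_sq))])

    def profile(self) -> np.ndarray:
        """delta_sq normalized by its value nearest t = T/2."""
        mid = int(np.argmin(np.abs(self.t - self.T / 2.0)))
        return self.delta_sq / self.delta_sq[mid]


def bridge_ensemble(params: WalkParams, z0, zT, T: float, tol: float,
                    n_accept: int, rng: np.random.Generator | None = None,
                    batch: int = 4096, min_rate: float = 1e-5,
                    ) -> BridgeEnsemble:
    """Rejection-sample walks from z0 conditioned to end within tol of zT.

    Accepted paths are re-pinned on their own endpoints: the deviation at
    interior step time t is measured from the chord point
    ``mu_B(t) = z0 + (z_end - z0) * t/T`` of each path, then averaged across
    paths per time bin.  Aborts when the running acceptance rate falls below
    ``min_rate`` (the tolerance is then too tight for the walk's spread).
    """
    if not tol > 0:
        raise ValueError("tol must be > 0")
    rng = np.random.default_rng(params.seed) if rng is None else rng
    n_steps = int(round(T / params.step_dt))
    if n_steps < 2:
        raise ValueError("T must span at least 2 steps")
    z0 = np.asarray(z0, dtype=float)
    zT = np.asarray(zT, dtype=float)
    n_acc, n_tried = 0, 0
    sums = np.zeros(n_steps - 1)
    while n_acc < n_accept:
        pos = simulate_paths(params, n_steps, batch, rng, start=z0)
        n_tried += batch
        end = pos[:, -1]
        ok = np.hypot(end[:, 0] - zT[0], end[:, 1] - zT[1]) <= tol
        sel = pos[ok]
        if len(sel) > n_accept - n_acc:
            sel = sel[: n_accept - n_acc]
        if len(sel):
            frac = (np.arange(1, n_steps) / n_steps)[None, :, None]
            mu = z0 + (sel[:, -1:, :] - z0) * frac
            d2 = np.sum((sel[:, 1:-1, :] - mu[:, : n_steps - 1]) ** 2, axis=-1)
            # mu above spans interior times 1..n_steps-1
            sums += d2.sum(axis=0)
            n_acc += len(sel)
        if n_tried >= 10 * batch and n_acc / n_tried < min_rate:
            raise RuntimeError(
                f"acceptance rate {n_acc / n_tried:.2e} below {min_rate:g}; "
                "enlarge tol (e.g. a larger multiple of sqrt(2*D*T))")
    t = np.arange(1, n_steps) * params.step_dt
    return BridgeEnsemble(t, sums / n_acc, n_acc, n_tried, T, tol)
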