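"""Diffusion-coefficient and drift-speed estimation from relocation triplets.

For a triplet of successive relocations z_{i-1}, z_i, z_{i+1} with activity
times T_i, T_{i+1}, treating the middle fix as if it were missing gives its
bridge expectation mu_B = z_{i-1} + (z_{i+1} - z_{i-1}) * T_i/(T_i + T_{i+1})
and E[delta^2] = 4 D T_i T_{i+1} / (T_i + T_{i+1}), where delta is the
distance between z_i and mu_B.  Averaging the per-couple unbiased ratios
delta^2 (T_i + T_{i+1}) / (4 T_i T_{i+1}) over the retained couples estimates
the diffusion coefficient D; restricting couples (or single segments, for
drift speeds via E[L^2] = v^2 T^2 + 4 D T) to those fully inside one habitat
type yields habitat-specific estimates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .raster import HabitatMap

__all__ = [
    "DiffusionEstimate",
    "DriftEstimate",
    "diffusion_couples",
    "estimate_d",
    "estimate_d_by_habitat",
    "beta_from_d",
    "display_beta",
    "segment_habitat",
    "estimate_drift_speeds",
]

logger = logging.getLogger(__name__)

COUPLE_COLUMNS = ["i", "delta_sq", "T1", "T2", "d_per_couple"]


@dataclass
class DiffusionEstimate:
    """Diffusion coefficient estimate and its per-couple diagnostics."""

    D_hat: float  # m^2/min; nan when undefined
    n_couples: int
    couples: pd.DataFrame = field(repr=False, default=None)
    habitat_code: int | None = None

    @property
    def defined(self) -> bool:
        return self.n_couples > 0

    def beta(self, T_max: float) -> float:
        return beta_from_d(self.D_hat, T_max) if self.defined else float("nan")


@dataclass
class DriftEstimate:
    """Habitat-specific squared drift speed estimate."""

    habitat_code: int | None
    v_sq: float  # m^2/min^2; may legitimately be negative
    n_segments: int

    @property
    def defined(self) -> bool:
        return self.n_segments > 0

    @property
    def v(self) -> float:
        """Drift speed (m/min); nan when v_sq < 0 or no segments."""
        if not self.defined or self.v_sq < 0:
            return float("nan")
        return float(np.sqrt(self.v_sq))


def _couple_frame(segments: pd.DataFrame) -> pd.DataFrame:
    """Pairs of contiguous segment rows (end fix of the first is the start
    fix of the second, same animal)."""
    a = segments.iloc[:-1].reset_index()
    b = segments.iloc[1:].reset_index(drop=True)
    contiguous = (
        (a["id"].to_numpy() == b["id"].to_numpy())
        & (a["t1"].to_numpy() == b["t0"].to_numpy())
        & np.isclose(a["x1"].to_numpy(), b["x0"].to_numpy())
        & np.isclose(a["y1"].to_numpy(), b["y0"].to_numpy())
    )
    return a[contiguous].reset_index(drop=True), b[contiguous].reset_index(drop=True)


def diffusion_couples(segments: pd.DataFrame, T_max: float) -> pd.DataFrame:
    """Retained couples of consecutive segments with their delta^2 values.

    A couple is retained when the drift can plausibly be taken constant
    across both segments: T_R(i) + T_R(i+1) <= T_max, both activity times
    positive, and neither the activity times nor the lengths differ by more
    than a factor of two (T_i <= 2 T_{i+1}, T_i >= T_{i+1}/2, likewise for
    L).  ``d_per_couple`` is the per-couple unbiased D estimate.
    """
    segments = segments.reset_index(drop=True)
    a, b = _couple_frame(segments)
    T1, T2 = a["T"].to_numpy(), b["T"].to_numpy()
    L1, L2 = a["L"].to_numpy(), b["L"].to_numpy()
    keep = (
        (a["T_R"].to_numpy() + b["T_R"].to_numpy() <= T_max)
        & (T1 > 0) & (T2 > 0)
        & (T1 <= 2 * T2) & (T1 >= T2 / 2)
        & (L1 <= 2 * L2) & (L1 >= L2 / 2)
    )
    # immobile-but-active segments flagged for null diffusion must not feed D,
    # and segments already excluded (short, resting, too long) never do
    if "null_d" in a:
        keep &= ~a["null_d"].to_numpy() & ~b["null_d"].to_numpy()
    if "included" in a:
        keep &= a["included"].to_numpy() & b["included"].to_numpy()
    a, b = a[keep].reset_index(drop=True), b[keep].reset_index(drop=True)
    T1, T2 = T1[keep], T2[keep]
    frac = T1 / (T1 + T2)
    mu_x = a["x0"].to_numpy() + (b["x1"].to_numpy() - a["x0"].to_numpy()) * frac
    mu_y = a["y0"].to_numpy() + (b["y1"].to_numpy() - a["y0"].to_numpy()) * frac
    delta_sq = (a["x1"].to_numpy() - mu_x) ** 2 + (a["y1"].to_numpy() - mu_y) ** 2
    return pd.DataFrame({
        "i": a["index"].to_numpy(),
        "delta_sq": delta_sq, "T1": T1, "T2": T2,
        "d_per_couple": delta_sq * (T1 + T2) / (4.0 * T1 * T2),
    })


def estimate_d(couples: pd.DataFrame, aggregation: str = "mean",
               habitat_code: int | None = None) -> DiffusionEstimate:
    """Diffusion coefficient from retained couples.

    ``aggregation="mean"`` averages the per-couple unbiased estimates
    (default, keeps per-couple diagnostics meaningful); ``"pooled"`` instead
    forms sum(delta^2) / sum(4 T1 T2 / (T1 + T2)) as a sensitivity check.
    """
    if aggregation not in ("mean", "pooled"):
        raise ValueError(f"unknown aggregation {aggregation!r}")
    n = len(couples)
    if n == 0:
        logger.warning("no retained couples; D undefined")
        return DiffusionEstimate(float("nan"), 0, couples, habitat_code)
    if aggregation == "mean":
        d_hat = float(couples["d_per_couple"].mean())
    else:
        t1, t2 = couples["T1"].to_numpy(), couples["T2"].to_numpy()
        d_hat = float(couples["delta_sq"].sum()
                      / np.sum(4.0 * t1 * t2 / (t1 + t2)))
    return DiffusionEstimate(d_hat, n, couples, habitat_code)


def beta_from_d(D: float, T_max: float) -> float:
    """Upper movement standard deviation beta_Tmax = sqrt(D*T_max/2) (m)."""
    if D < 0:
        raise ValueError("D must be >= 0")
    return float(np.sqrt(D * T_max / 2.0))


def display_beta(D: float, T_max: float) -> float:
    """beta_Tmax rounded to the nearest 10 m, the customary display precision."""
    return float(np.round(beta_from_d(D, T_max) / 10.0) * 10.0)


def segment_habitat(segments: pd.DataFrame, habitat: HabitatMap,
                    sample_step: float) -> np.ndarray:
    """Habitat code of each segment, or the map's nodata when mixed.

    A segment is "fully encompassed" in a habitat type when both endpoints
    and points sampled every ``sample_step`` metres along its chord all carry
    the same code (and none is nodata).
    """
    if not sample_step > 0:
        raise ValueError("sample_step must be > 0")
    x0, y0 = segments["x0"].to_numpy(), segments["y0"].to_numpy()
    x1, y1 = segments["x1"].to_numpy(), segments["y1"].to_numpy()
    L = segments["L"].to_numpy()
    out = np.full(len(segments), habitat.nodata, dtype=int)
    for k in range(len(segments)):
        n = max(1, int(np.ceil(L[k] / sample_step)))
        f = np.linspace(0.0, 1.0, n + 1)
        codes = habitat.code_at(x0[k] + (x1[k] - x0[k]) * f,
                                y0[k] + (y1[k] - y0[k]) * f)
        if codes[0] != habitat.nodata and np.all(codes == codes[0]):
            out[k] = codes[0]
    return out


def estimate_d_by_habitat(segments: pd.DataFrame, habitat: HabitatMap,
                          T_max: float, sample_step: float,
                          aggregation: str = "mean",
                          ) -> dict[int, DiffusionEstimate]:
    """Habitat-specific diffusion coefficients D_H.

    Only couples whose two segments are both fully encompassed in the same
    habitat type contribute; habitats without a single qualifying couple get
    an undefined-flagged entry (n_couples = 0) so small samples stay visible.
    """
    segments = segments.reset_index(drop=True)
    seg_hab = segment_habitat(segments, habitat, sample_step)
    couples = diffusion_couples(segments, T_max)
    idx = couples["i"].to_numpy(dtype=int)
    hab1 = seg_hab[idx] if len(couples) else np.empty(0, dtype=int)
    hab2 = seg_hab[idx + 1] if len(couples) else np.empty(0, dtype=int)
    same = (hab1 == hab2) & (hab1 != habitat.nodata)
    out: dict[int, DiffusionEstimate] = {}
    for code in sorted(habitat.legend):
        sub = couples[same & (hab1 == code)].reset_index(drop=True)
        out[code] = estimate_d(sub, aggregation, habitat_code=code)
        if not out[code].defined:
            logger.warning("habitat %s: no qualifying couples, D_H undefined",
                           habitat.legend.get(code, code))
    return out


def estimate_drift_speeds(segments: pd.DataFrame, habitat: HabitatMap,
                          D, sample_step: float,
                          aggregation: str = "mean") -> list[DriftEstimate]:
    """Habitat-specific squared drift speeds via E[L^2] = v^2 T^2 + 4 D T.

    ``D`` is either a global scalar or a ``{code: D_H}`` mapping (undefined
    habitat entries fall back to nothing -- those habitats are skipped with a
    warning).  Negative v_sq values are reported as-is: they signal mainly
    diffusive movement in a habitat whose own diffusion coefficient is below
    the global one, and are informative rather than erroneous.
    """
    if aggregation not in ("mean", "pooled"):
        raise ValueError(f"unknown aggregation {aggregation!r}")
    segments = segments.reset_index(drop=True)
    seg_hab = segment_habitat(segments, habitat, sample_step)
    active = segments["T"].to_numpy() > 0
    if "included" in segments:
        active &= segments["included"].to_numpy()
    if "null_d" in segments:
        active &= ~segments["null_d"].to_numpy()
    out: list[DriftEstimate] = []
    for code in sorted(habitat.legend):
        if isinstance(D, dict):
            d_val = D.get(code, float("nan"))
            if not np.isfinite(d_val):
                logger.warning("habitat %s: no diffusion coefficient "
                               "available; drift speed skipped",
                               habitat.legend.get(code, code))
                out.append(DriftEstimate(code, float("nan"), 0))
                continue
        else:
            d_val = float(D)
        sel = active & (seg_hab == code)
        L = segments.loc[sel, "L"].to_numpy()
        T = segments.loc[sel, "T"].to_numpy()
        if len(L) == 0:
            out.append(DriftEstimate(code, float("nan"), 0))
            continue
        if aggregation == "mean":
            v_sq = float(np.mean((L**2 - 4.0 * d_val * T) / T**2))
        else:
            v_sq = float(np.sum(L**2 - 4.0 * d_val * T) / np.sum(T**2))
        out.append(DriftEstimate(code, v_sq, int(len(L))))
    return out
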