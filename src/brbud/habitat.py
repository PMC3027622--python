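"""Habitat availability, UD-weighted use, and normalized preferences.

Availability is the plain cell-count proportion of each habitat type inside
a reference area (by default the 95% isopleth of the UD); use is the
UD-mass-weighted proportion over the same area.  The normalized preference
of habitat H is its use/availability ratio rescaled so the ratios sum to
one: values above 1/K (K habitats) indicate selection, below indicate
avoidance.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .estimators import DiffusionEstimate, DriftEstimate
from .raster import HabitatMap
from .ud import UDRaster, isopleth_mask

__all__ = ["availability", "ud_weighted_use", "preference_table",
           "habitat_preferences"]

logger = logging.getLogger(__name__)


def _check_mask(hab: HabitatMap, mask: np.ndarray) -> np.ndarray:
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != hab.grid.shape:
        raise ValueError("mask shape does not match habitat grid")
    if not mask.any():
        raise ValueError("empty mask")
    return mask


def availability(hab: HabitatMap, mask: np.ndarray) -> pd.Series:
    """Non-weighted proportion of each habitat type inside the mask.

    NODATA cells are excluded from the denominator.  Returns fractions
    summing to 1, indexed by habitat code.
    """
    mask = _check_mask(hab, mask)
    codes = hab.codes[mask]
    codes = codes[codes != hab.nodata]
    if codes.size == 0:
        raise ValueError("mask contains only NODATA cells")
    out = pd.Series(0.0, index=sorted(hab.legend))
    vals, counts = np.unique(codes, return_counts=True)
    for v, c in zip(vals, counts):
        out.loc[int(v)] = c / codes.size
    return out


def ud_weighted_use(ud: UDRaster, hab: HabitatMap, mask: np.ndarray) -> pd.Series:
    """UD-weighted proportion of each habitat type inside the mask."""
    if not ud.normalized:
        raise ValueError("UD must be normalized")
    hab = hab.resample_to(ud.grid)
    mask = _check_mask(hab, mask)
    sel = mask & (hab.codes != hab.nodata)
    total = float(ud.values[sel].sum())
    if total <= 0:
        raise ValueError("no UD mass inside the mask")
    out = pd.Series(0.0, index=sorted(hab.legend))
    for code in out.index:
        out.loc[code] = float(ud.values[sel & (hab.codes == code)].sum()) / total
    return out


def preference_table(avail: pd.Series, use: pd.Series,
                     d_estimates: dict[int, DiffusionEstimate] | None = None,
                     drift: list[DriftEstimate] | None = None,
                     legend: dict[int, str] | None = None) -> pd.DataFrame:
    """Per-habitat availability, use, and unit-sum normalized preference.

    Habitats with zero availability inside the mask are dropped with a
    warning (their selection ratio is undefined).  Optional diffusion and
    drift estimates are joined in, with their sample sizes, so that values
    resting on few couples or segments can be read with due caution.
    """
    common = [c for c in avail.index if c in use.index]
    rows = []
    for code in common:
        if avail.loc[code] <= 0:
            if use.loc[code] > 0:
                logger.warning("habitat %s has use but zero availability; "
                               "dropped from the preference table", code)
            continue
        rows.append((code, avail.loc[code], use.loc[code],
                     use.loc[code] / avail.loc[code]))
    if not rows:
        raise ValueError("no habitat with positive availability")
    df = pd.DataFrame(rows, columns=["code", "availability", "use", "ratio"])
    total = df["ratio"].sum()
    if total <= 0:
        raise ValueError("all use/availability ratios are zero")
    df["normalized_preference"] = df["ratio"] / total
    df["availability_pct"] = 100.0 * df["availability"]
    df["use_pct"] = 100.0 * df["use"]
    if legend:
        df.insert(1, "habitat", df["code"].map(lambda c: legend.get(c, str(c))))
    if d_estimates is not None and isinstance(d_estimates, dict):
        df["D_H"] = df["code"].map(
            lambda c: d_estimates[c].D_hat if c in d_estimates else np.nan)
        df["n_couples"] = df["code"].map(
            lambda c: d_estimates[c].n_couples if c in d_estimates else 0)
    if drift is not None:
        by_code = {e.habitat_code: e for e in drift}
        df["v"] = df["code"].map(
            lambda c: by_code[c].v if c in by_code else np.nan)
        df["v_sq"] = df["code"].map(
            lambda c: by_code[c].v_sq if c in by_code else np.nan)
        df["n_segments"] = df["code"].map(
            lambda c: by_code[c].n_segments if c in by_code else 0)
    return df.set_index("code")


def habitat_preferences(ud: UDRaster, hab: HabitatMap, level: float = 95.0,
                        d_estimates: dict[int, DiffusionEstimate] | None = None,
                        drift: list[DriftEstimate] | None = None,
                        ) -> pd.DataFrame:
    """One-call preference table over the ``level``% isopleth of the UD."""
    hab = hab.resample_to(ud.grid)
    mask = isopleth_mask(ud, level)
    avail = availability(hab, mask)
    use = ud_weighted_use(ud, hab, mask)
    return preference_table(avail, use, d_estimates, drift, hab.legend)
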