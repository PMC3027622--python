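"""Track ingest, segment construction and filtering, stationarity diagnostic.

A *track* is a pandas DataFrame of fixes with columns ``id`` (animal),
``t`` (absolute time, minutes), ``x``/``y`` (projected planar metres) and
``p`` (proportion of the recording interval ending at the fix during which
the animal was active, in [0, 1]).  A *segments* frame holds one row per
pair of successive fixes of the same animal, carrying the recording interval
``T_R``, activity time ``T = p * T_R``, Euclidean length ``L``, and the
inclusion flags used by every downstream computation.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd

__all__ = [
    "read_track",
    "write_track",
    "build_segments",
    "filter_segments",
    "apply_global_mode",
    "sliding_window_stats",
    "EXCLUSION_REASONS",
]

logger = logging.getLogger(__name__)

EXCLUSION_REASONS = ("none", "exceeds_Tmax", "below_Lmin", "resting", "user")

FIX_COLUMNS = ["id", "t", "x", "y", "p"]

SEGMENT_COLUMNS = [
    "id", "t0", "t1", "x0", "y0", "x1", "y1",
    "T_R", "T", "L", "p", "included", "reason", "null_d",
]

_DEFAULT_MAPPING = {"id": "id", "time": "time", "x": "x", "y": "y",
                    "activity": "activity"}


def _times_to_minutes(series: pd.Series) -> pd.Series:
    """Numeric timestamps are taken as minutes; otherwise parse as datetimes
    and convert to minutes elapsed since the earliest timestamp in the file."""
    numeric = pd.to_numeric(series, errors="coerce")
    if numeric.notna().all():
        return numeric.astype(float)
    parsed = pd.to_datetime(series, errors="coerce", format="ISO8601")
    bad = numeric.isna() & parsed.isna()
    if bad.any():
        row = series.index[bad][0]
        raise ValueError(f"unparseable timestamp at data row {row}: "
                         f"{series.loc[row]!r}")
    if parsed.isna().any():  # mix of numbers and datetimes
        row = series.index[parsed.isna()][0]
        raise ValueError(f"inconsistent timestamp format at data row {row}: "
                         f"{series.loc[row]!r}")
    return (parsed - parsed.min()).dt.total_seconds() / 60.0


def read_track(path, columns: dict[str, str] | None = None,
               sep: str = ",") -> pd.DataFrame:
    """Read a delimited track file into a fixes frame.

    Parameters
    ----------
    path : str or file-like
        Delimited text with a header row.
    columns : dict, optional
        Maps the roles ``id``, ``time``, ``x``, ``y``, ``activity`` to the
        column names in the file.  Roles absent from the file: ``id``
        defaults to a single animal "a1"; a missing activity column sets
        p = 1 everywhere (with a warning).
    """
    mapping = {**_DEFAULT_MAPPING, **(columns or {})}
    df = pd.read_csv(path, sep=sep)
    if df.empty:
        raise ValueError(f"track file {path} contains no data rows")
    for role in ("x", "y", "time"):
        if mapping[role] not in df.columns:
            raise ValueError(f"required column {mapping[role]!r} (role {role}) "
                             f"not found in {path}")
    out = pd.DataFrame({
        "id": df[mapping["id"]].astype(str) if mapping["id"] in df.columns
        else "a1",
        "t": _times_to_minutes(df[mapping["time"]]),
        "x": pd.to_numeric(df[mapping["x"]]),
        "y": pd.to_numeric(df[mapping["y"]]),
    })
    if mapping["activity"] in df.columns:
        out["p"] = pd.to_numeric(df[mapping["activity"]]).astype(float)
    else:
        out["p"] = 1.0
        warnings.warn("no activity column found; assuming fully active "
                      "intervals (p = 1)", stacklevel=2)
    bad = ~np.isfinite(out[["t", "x", "y", "p"]]).all(axis=1)
    if bad.any():
        raise ValueError(f"non-finite value at data row {int(np.argmax(bad.values))}")
    if ((out["p"] < 0) | (out["p"] > 1)).any():
        raise ValueError("activity proportion outside [0, 1]")
    for animal, grp in out.groupby("id"):
        if grp["t"].duplicated().any():
            t_dup = grp.loc[grp["t"].duplicated(), "t"].iloc[0]
            raise ValueError(f"duplicate timestamp t={t_dup:g} for animal {animal}")
        if not grp["t"].is_monotonic_increasing:
            logger.warning("fixes for animal %s are out of time order; sorting",
                           animal)
    return out.sort_values(["id", "t"], kind="mergesort").reset_index(drop=True)


def write_track(fixes: pd.DataFrame, path, sep: str = ",") -> None:
    """Write a fixes frame back to delimited text (roles as column names)."""
    fixes[FIX_COLUMNS].rename(columns={"t": "time", "p": "activity"}).to_csv(
        path, sep=sep, index=False)


def build_segments(fixes: pd.DataFrame) -> pd.DataFrame:
    """One segment per pair of successive fixes of the same animal.

    All segments start included with reason "none"; filtering is separate.
    The activity proportion of the interval is the ``p`` attached to the
    segment's *end* fix.
    """
    if len(fixes) < 2:
        raise ValueError("need at least 2 fixes to build segments")
    parts = []
    for animal, grp in fixes.groupby("id", sort=False):
        if len(grp) < 2:
            continue
        a = grp.iloc[:-1].reset_index(drop=True)
        b = grp.iloc[1:].reset_index(drop=True)
        T_R = (b["t"] - a["t"]).to_numpy()
        if np.any(T_R <= 0):
            raise ValueError(f"non-increasing timestamps for animal {animal}")
        L = np.hypot(b["x"].to_numpy() - a["x"].to_numpy(),
                     b["y"].to_numpy() - a["y"].to_numpy())
        parts.append(pd.DataFrame({
            "id": animal,
            "t0": a["t"].to_numpy(), "t1": b["t"].to_numpy(),
            "x0": a["x"].to_numpy(), "y0": a["y"].to_numpy(),
            "x1": b["x"].to_numpy(), "y1": b["y"].to_numpy(),
            "T_R": T_R, "T": b["p"].to_numpy() * T_R, "L": L,
            "p": b["p"].to_numpy(),
            "included": True, "reason": "none", "null_d": False,
        }))
    if not parts:
        raise ValueError("no animal has 2 or more fixes")
    return pd.concat(parts, ignore_index=True)[SEGMENT_COLUMNS]


def filter_segments(segments: pd.DataFrame, T_max: float, L_min: float = 0.0,
                    immobile_active_mode: str = "drop") -> pd.DataFrame:
    """Flag segments excluded from UD computation.

    Order of precedence: recording intervals longer than ``T_max`` are
    excluded outright (their activity time no longer enters any downstream
    sum); fully resting segments (T = 0) are excluded as "resting"; segments
    shorter than ``L_min`` are excluded as "below_Lmin" under mode "drop",
    or kept and flagged for a null diffusion coefficient under mode
    "keep_null_D" (the choice for animals that feed intensively while nearly
    immobile).  Idempotent; returns a flagged copy.
    """
    if not T_max > 0:
        raise ValueError("T_max must be > 0")
    if L_min < 0:
        raise ValueError("L_min must be >= 0")
    if immobile_active_mode not in ("drop", "keep_null_D"):
        raise ValueError(f"unknown immobile_active_mode {immobile_active_mode!r}")
    out = segments.copy()
    out["included"] = True
    out["reason"] = "none"
    out["null_d"] = out["null_d"] if "null_d" in out else False

    too_long = out["T_R"].to_numpy() > T_max
    out.loc[too_long, ["included", "reason"]] = [False, "exceeds_Tmax"]

    resting = (~too_long) & (out["T"].to_numpy() <= 0)
    out.loc[resting, ["included", "reason"]] = [False, "resting"]

    short = (~too_long) & (~resting) & (out["L"].to_numpy() < L_min)
    if immobile_active_mode == "drop":
        out.loc[short, ["included", "reason"]] = [False, "below_Lmin"]
    else:
        out.loc[short, "null_d"] = True

    n_excl = int((~out["included"]).sum())
    t_removed = float(out.loc[~out["included"], "T"].sum())
    logger.info("filter_segments: %d/%d segments excluded, %.1f min of "
                "activity time removed", n_excl, len(out), t_removed)
    return out


def apply_global_mode(segments: pd.DataFrame,
                      resting_threshold: float = 0.0) -> pd.DataFrame:
    """Switch from an active-time UD to a global (active + resting) UD.

    Every segment is treated as fully active (T = T_R) so that resting time
    is spread around the fixes instead of being discarded; segments whose
    original activity proportion is at or below ``resting_threshold`` are
    flagged for a null diffusion coefficient (the animal was presumed
    stationary, so no movement variance should be inflated along them).
    """
    out = segments.copy()
    out["null_d"] = out["null_d"] | (out["p"] <= resting_threshold)
    out["T"] = out["T_R"]
    out["p"] = 1.0
    return out


def sliding_window_stats(fixes: pd.DataFrame, window: float,
                         step: float) -> pd.DataFrame:
    """Sliding-window mean and variance of x and y along a track.

    The diagnostic used to delineate stationary home-range periods by eye:
    durable changes in the mean or variance of either coordinate mark range
    shifts.  Windows are half-open ``[centre - w/2, centre + w/2)``, advance
    by ``step`` minutes, and use population variance; windows holding fewer
    than two fixes are omitted.
    """
    if not window > 0 or not step > 0:
        raise ValueError("window and step must be > 0")
    rows = []
    for animal, grp in fixes.groupby("id", sort=False):
        t = grp["t"].to_numpy()
        x, y = grp["x"].to_numpy(), grp["y"].to_numpy()
        if len(t) == 0:
            continue
        centres = np.arange(t[0] + window / 2.0, t[-1] - window / 2.0 + 1e-9,
                            step)
        for c in centres:
            sel = (t >= c - window / 2.0) & (t < c + window / 2.0)
            n = int(sel.sum())
            if n < 2:
                logger.info("window centred at %.1f min for %s has %d fix(es);"
                            " omitted", c, animal, n)
                continue
            rows.append((animal, float(c), window, n,
                         float(x[sel].mean()), float(y[sel].mean()),
                         float(x[sel].var()), float(y[sel].var())))
    return pd.DataFrame(rows, columns=["id", "centre", "window", "n_fixes",
                                       "mean_x", "mean_y", "var_x", "var_y"])
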