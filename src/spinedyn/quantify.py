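"""Ratio normalization of two-channel spine ROI intensities.

Every measure downstream of the raw ROI means is a ratio of
background-subtracted intensities: the spine SEP-GluA1 (green) or spine
dsRed (red, a proxy for spine size) ROI, each minus its own background
ROI, divided by the background-subtracted dsRed intensity of the adjacent
dendritic shaft.  Because day-to-day imaging gain multiplies every ROI of
a session identically, it cancels in the ratio.

Further normalization modes re-express a spine's per-session ratios
relative to its day-1 value, to the mean of the three pre-deprivation
baseline sessions, to the dendrite mean at each session, or as
day-over-day change ratios.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .schedules import Schedule

__all__ = [
    "FLAG_OK",
    "FLAG_FLOORED",
    "FLAG_BAD_DENOM",
    "normalize_spine_value",
    "ratio_table",
    "normalize_trace",
    "normalize_traces",
    "relative_to_dendrite_mean",
    "add_relative_to_dendrite_mean",
    "daily_change",
    "daily_change_table",
    "dendrite_summary",
    "extract_roi_intensities",
]

log = logging.getLogger(__name__)

FLAG_OK = "ok"
FLAG_FLOORED = "floored_numerator"
FLAG_BAD_DENOM = "invalid_denominator"

#: floor applied to non-positive background-subtracted numerators
EPS_FLOOR = 1e-6

NORMALIZATION_MODES = (
    "raw_ratio", "to_day1", "to_baseline_mean", "to_dendrite_mean",
    "daily_change",
)


def normalize_spine_value(spine_raw, spine_bg, shaft_raw, shaft_bg,
                          floor: float = EPS_FLOOR):
    """Background-subtracted spine ROI over background-subtracted shaft ROI.

    Returns ``(value, flag)`` arrays (or scalars for scalar input).  A
    non-positive denominator yields NaN flagged ``invalid_denominator``;
    a non-positive numerator is clipped to ``floor`` and flagged
    ``floored_numerator`` so trace shapes stay aligned.
    """
    spine_raw = np.asarray(spine_raw, dtype=float)
    spine_bg = np.asarray(spine_bg, dtype=float)
    shaft_raw = np.asarray(shaft_raw, dtype=float)
    shaft_bg = np.asarray(shaft_bg, dtype=float)

    num = spine_raw - spine_bg
    den = shaft_raw - shaft_bg
    flags = np.full(num.shape, FLAG_OK, dtype=object)
    bad_den = ~(den > 0)
    floored = (num <= 0) & ~bad_den & ~np.isnan(num)
    num = np.where(floored, floor, num)
    with np.errstate(divide="ignore", invalid="ignore"):
        value = np.where(bad_den, np.nan, num / np.where(bad_den, 1.0, den))
    flags[np.asarray(bad_den) & ~np.isnan(spine_raw)] = FLAG_BAD_DENOM
    flags[np.asarray(floored)] = FLAG_FLOORED
    if value.ndim == 0:
        return float(value), str(flags[()])
    return value, flags


def ratio_table(spine_table: pd.DataFrame, floor: float = EPS_FLOOR) -> pd.DataFrame:
    """Shaft-normalize every present spine x session row of a long table.

    Returns a tidy frame with ``sglua1`` (green/shaft) and ``size``
    (red/shaft) columns plus per-channel quality flags; rows where the
    spine is absent are dropped.
    """
    df = spine_table.loc[spine_table["present"].astype(bool)].copy()
    g, gf = normalize_spine_value(
        df["green_spine"], df["bg_green_spine"],
        df["red_shaft"], df["bg_red_shaft"], floor,
    )
    r, rf = normalize_spine_value(
        df["red_spine"], df["bg_red_spine"],
        df["red_shaft"], df["bg_red_shaft"], floor,
    )
    out = df[["spine_id", "dendrite_id", "neuron_id", "session",
              "z_um", "dist_branch_um"]].copy()
    out["sglua1"] = g
    out["size"] = r
    out["sglua1_flag"] = gf
    out["size_flag"] = rf
    n_flagged = int((gf != FLAG_OK).sum() + (rf != FLAG_OK).sum())
    if n_flagged:
        log.info("ratio_table: %d flagged ROI measurements", n_flagged)
    return out


def _valid(series: pd.Series, flags: pd.Series) -> pd.Series:
    return series.where((flags == FLAG_OK) & series.notna())


def normalize_trace(values: pd.Series, mode: str, schedule: Schedule) -> pd.Series:
    """Normalize one spine's per-session ratio trace.

    ``values`` is indexed by session label (missing sessions absent or
    NaN).  Flagged/invalid entries must already be NaN.  Returns NaN-filled
    series over the full schedule; returns all-NaN if the reference
    (day 1 or the complete baseline window) is unavailable.
    """
    v = values.reindex(list(schedule.sessions)).astype(float)
    if mode == "raw_ratio":
        return v
    if mode == "to_day1":
        ref = v.iloc[0]
        if not np.isfinite(ref) or ref <= 0:
            return pd.Series(np.nan, index=v.index)
        return v / ref
    if mode == "to_baseline_mean":
        base = v.loc[list(schedule.baseline)]
        if base.isna().any():
            return pd.Series(np.nan, index=v.index)
        ref = base.mean()
        if ref <= 0:
            return pd.Series(np.nan, index=v.index)
        return v / ref
    if mode == "daily_change":
        return daily_change(v, schedule)
    raise ValueError(f"unknown normalization mode {mode!r}")


def normalize_traces(ratios: pd.DataFrame, mode: str, schedule: Schedule,
                     value_cols: tuple[str, ...] = ("sglua1", "size")
                     ) -> pd.DataFrame:
    """Apply :func:`normalize_trace` per spine to a ratio table.

    ``to_dendrite_mean`` is handled per dendrite x session (see
    :func:`relative_to_dendrite_mean`).  Output is long format with a
    ``mode`` column; spines lacking the reference sessions are dropped
    and counted in the log.
    """
    if mode not in NORMALIZATION_MODES:
        raise ValueError(
            f"unknown normalization mode {mode!r}; valid: {NORMALIZATION_MODES}"
        )
    df = ratios.copy()
    for col in value_cols:
        df[col] = _valid(df[col], df[f"{col}_flag"])

    if mode == "to_dendrite_mean":
        out = df.copy()
        for col in value_cols:
            out[col] = (
                df.groupby(["dendrite_id", "session"])[col]
                .transform(lambda s: s / s.mean())
            )
        out["mode"] = mode
        return out[["spine_id", "dendrite_id", "neuron_id", "session",
                    *value_cols, "mode"]]

    meta = df.drop_duplicates("spine_id").set_index("spine_id")[
        ["dendrite_id", "neuron_id"]]
    sessions = list(schedule.sessions)
    norm_cols = {}
    n_excluded = 0
    for col in value_cols:
        piv = df.pivot(index="spine_id", columns="session", values=col)
        piv = piv.reindex(columns=sessions)
        if mode == "to_day1":
            ref = piv.iloc[:, 0].where(piv.iloc[:, 0] > 0)
            out_piv = piv.div(ref, axis=0)
        elif mode == "to_baseline_mean":
            base = piv[list(schedule.baseline)]
            ref = base.mean(axis=1).where(base.notna().all(axis=1))
            ref = ref.where(ref > 0)
            out_piv = piv.div(ref, axis=0)
        elif mode == "raw_ratio":
            out_piv = piv
        else:  # daily_change
            prev = piv.shift(axis=1)
            out_piv = piv / prev.where(prev > 0)
            keep = [b for a, b in zip(sessions[:-1], sessions[1:])
                    if schedule.is_consecutive(a, b)]
            out_piv.loc[:, [s for s in sessions if s not in keep]] = np.nan
        n_excluded = max(n_excluded, int(out_piv.isna().all(axis=1).sum()))
        norm_cols[col] = out_piv.stack(future_stack=True)
    if n_excluded:
        log.info("normalize_traces(%s): %d spines lacked the reference "
                 "session(s) and were excluded", mode, n_excluded)
    out = pd.DataFrame(norm_cols).rename_axis(
        ["spine_id", "session"]).reset_index()
    out = out.join(meta, on="spine_id")
    out["mode"] = mode
    return out[["spine_id", "dendrite_id", "neuron_id", "session",
                *value_cols, "mode"]].dropna(subset=list(value_cols), how="all")


def relative_to_dendrite_mean(values) -> np.ndarray:
    """Scale spine values on one dendrite at one session to mean 1.

    The dendrite average is the arithmetic mean over valid spines.
    """
    v = np.asarray(values, dtype=float)
    valid = np.isfinite(v)
    if not valid.any():
        raise ValueError("no valid spine values on this dendrite")
    return v / v[valid].mean()


def add_relative_to_dendrite_mean(df: pd.DataFrame, col: str,
                                  out_col: str | None = None) -> pd.DataFrame:
    """Per (dendrite, session) relative level column added to a long table."""
    out_col = out_col or f"{col}_rel"
    df = df.copy()
    df[out_col] = df.groupby(["dendrite_id", "session"])[col].transform(
        lambda s: s / s.mean()
    )
    return df


def daily_change(values: pd.Series, schedule: Schedule) -> pd.Series:
    """Day-over-day change ratios ``value[t] / value[t-1]``.

    Emitted only for transitions between consecutive calendar days with
    both sessions valid; indexed by the later session of each transition.
    """
    v = values.reindex(list(schedule.sessions)).astype(float)
    out = pd.Series(np.nan, index=v.index)
    for a, b in zip(schedule.sessions[:-1], schedule.sessions[1:]):
        if not schedule.is_consecutive(a, b):
            continue
        if np.isfinite(v[a]) and np.isfinite(v[b]) and v[a] > 0:
            out[b] = v[b] / v[a]
    return out


def daily_change_table(ratios: pd.DataFrame, schedule: Schedule,
                       value_cols: tuple[str, ...] = ("sglua1", "size")
                       ) -> pd.DataFrame:
    """Long table of per-spine daily changes for the given value columns."""
    out = normalize_traces(ratios, "daily_change", schedule, value_cols)
    return out.dropna(subset=list(value_cols), how="all")


def dendrite_summary(norm: pd.DataFrame, col: str = "sglua1") -> pd.DataFrame:
    """Geometric mean of per-spine values per dendrite x session.

    Callers restrict the input to the spine population the figure uses
    (typically persistent spines).
    """
    rows = []
    for (dendrite_id, session), sub in norm.groupby(["dendrite_id", "session"]):
        vals = sub[col].dropna()
        vals = vals[vals > 0]
        if len(vals) == 0:
            continue
        rows.append(dict(
            dendrite_id=dendrite_id, session=session,
            value=float(sps.gmean(vals)), n_spines=int(len(vals)),
        ))
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# image-domain entry point

@dataclass
class RoiMaskSet:
    """Pixel masks for one dendrite's ROIs in a rendered stack.

    ``masks`` maps ROI name (e.g. ``"spine/<spine_id>"``, ``"shaft"``,
    ``"bg/<name>"``) to a boolean array of the stack's spatial shape.
    """

    shape: tuple[int, int, int]  # (z, y, x)
    masks: dict[str, np.ndarray]


def extract_roi_intensities(stack: np.ndarray, masks: RoiMaskSet,
                            ) -> dict[str, dict[str, float]]:
    """Mean pixel value per ROI per channel.

    ``stack`` has shape (z, channel, y, x) with channel 0 = green
    (SEP-GluA1) and channel 1 = red (dsRed2).
    """
    if stack.ndim != 4 or stack.shape[1] != 2:
        raise ValueError("stack must have shape (z, 2, y, x)")
    spatial = (stack.shape[0], stack.shape[2], stack.shape[3])
    if masks.shape != spatial:
        raise ValueError(
            f"mask shape {masks.shape} does not match stack spatial shape "
            f"{spatial}"
        )
    out: dict[str, dict[str, float]] = {}
    for name, mask in masks.masks.items():
        if mask.shape != spatial:
            raise ValueError(f"mask {name!r} shape mismatch")
        if not mask.any():
            raise ValueError(f"mask {name!r} is empty")
        out[name] = {
            "green": float(stack[:, 0][mask].mean()),
            "red": float(stack[:, 1][mask].mean()),
        }
    return out
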