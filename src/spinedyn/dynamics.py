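"""Baseline-condition analyses: spine fate, persistence, intensity
dynamics (CV), cross-day stability, and size-fluorescence coupling.

All intensity comparisons here operate on shaft-normalized ratios,
usually re-expressed relative to the dendrite mean so that spines from
different dendrites are comparable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .schedules import Schedule

__all__ = [
    "SpineFate",
    "classify_spine_fate",
    "classify_fates",
    "persistence_fraction",
    "transient_intensity",
    "spine_cv",
    "cv_table",
    "cross_day_correlation",
    "size_fluorescence_coupling",
    "distribution_shift",
]

log = logging.getLogger(__name__)

FATES = ("persistent", "formed", "eliminated", "formed_and_eliminated")


@dataclass(frozen=True)
class SpineFate:
    spine_id: str
    fate: str
    first_detected: str
    last_detected: str
    n_present: int


def classify_spine_fate(presence: pd.Series, schedule: Schedule,
                        spine_id: str = "") -> SpineFate:
    """Assign persistent / formed / eliminated from a presence pattern.

    ``presence`` is indexed by session label.  A spine absent at an
    interior session but present before and after is treated as a
    detection failure (persistent with missing data), not as an
    elimination followed by re-formation; only the first and last
    detections matter.
    """
    p = presence.reindex(list(schedule.sessions)).fillna(False).astype(bool)
    if not p.any():
        raise ValueError(f"spine {spine_id!r} is never present")
    idx = np.flatnonzero(p.to_numpy())
    first, last = int(idx[0]), int(idx[-1])
    formed = first > 0
    eliminated = last < schedule.n_sessions - 1
    if formed and eliminated:
        fate = "formed_and_eliminated"
    elif formed:
        fate = "formed"
    elif eliminated:
        fate = "eliminated"
    else:
        fate = "persistent"
    return SpineFate(
        spine_id=spine_id, fate=fate,
        first_detected=schedule.sessions[first],
        last_detected=schedule.sessions[last],
        n_present=int(p.sum()),
    )


def classify_fates(spine_table: pd.DataFrame, schedule: Schedule) -> pd.DataFrame:
    """Fate classification for every spine of a long presence table.

    Vectorized equivalent of :func:`classify_spine_fate` applied per spine.
    """
    piv = (
        spine_table.pivot(index="spine_id", columns="session", values="present")
        .reindex(columns=list(schedule.sessions))
        .fillna(False).astype(bool)
    )
    if not piv.to_numpy().any(axis=1).all():
        bad = piv.index[~piv.to_numpy().any(axis=1)][0]
        raise ValueError(f"spine {bad!r} is never present")
    m = piv.to_numpy()
    n_s = schedule.n_sessions
    first = m.argmax(axis=1)
    last = n_s - 1 - m[:, ::-1].argmax(axis=1)
    fate = np.where(
        (first == 0) & (last == n_s - 1), "persistent",
        np.where(
            (first > 0) & (last < n_s - 1), "formed_and_eliminated",
            np.where(first > 0, "formed", "eliminated"),
        ),
    )
    sessions = np.array(schedule.sessions)
    meta = spine_table.drop_duplicates("spine_id").set_index("spine_id")
    out = pd.DataFrame(dict(
        spine_id=piv.index,
        dendrite_id=meta.loc[piv.index, "dendrite_id"].to_numpy(),
        neuron_id=meta.loc[piv.index, "neuron_id"].to_numpy(),
        fate=fate, first_detected=sessions[first], last_detected=sessions[last],
    )).reset_index(drop=True)
    return out


def persistence_fraction(fates: pd.DataFrame, schedule: Schedule) -> float:
    """Percent of first-session spines that persist through every session.

    The denominator is the spines already present at the first imaging
    session — the population whose survival the longitudinal experiment
    follows; spines formed later are tracked but, being unable to span
    the whole window, are not part of the survival denominator.
    """
    if len(fates) == 0:
        raise ValueError("no spine fates supplied")
    day1 = fates.loc[fates["first_detected"] == schedule.sessions[0]]
    if len(day1) == 0:
        raise ValueError("no spines present at the first session")
    return 100.0 * float((day1["fate"] == "persistent").mean())


def transient_intensity(rel_values: pd.DataFrame, fates: pd.DataFrame,
                        schedule: Schedule, col: str = "sglua1") -> pd.DataFrame:
    """Event-time relative sGluA1 of transient spines plus peri-event traces.

    For each formed (eliminated) spine, ``event_value`` is its
    relative-to-dendrite-mean level at first (last) detection;
    ``event_offset`` columns give the peri-event trajectory (sessions
    counted from the event).  Persistent spines are rejected.
    """
    fmap = fates.set_index("spine_id")
    rows = []
    for spine_id, sub in rel_values.groupby("spine_id"):
        if spine_id not in fmap.index:
            continue
        fate = fmap.loc[spine_id, "fate"]
        if fate == "persistent":
            raise ValueError(f"spine {spine_id!r} is persistent")
        trace = sub.set_index("session")[col].reindex(list(schedule.sessions))
        events = []
        if fate in ("formed", "formed_and_eliminated"):
            events.append(("formed", fmap.loc[spine_id, "first_detected"]))
        if fate in ("eliminated", "formed_and_eliminated"):
            events.append(("eliminated", fmap.loc[spine_id, "last_detected"]))
        for event, session in events:
            t0 = schedule.index(session)
            for t, s in enumerate(schedule.sessions):
                if np.isfinite(trace[s]):
                    rows.append(dict(
                        spine_id=spine_id, event=event,
                        event_session=session, session=s,
                        event_offset=t - t0, value=float(trace[s]),
                        is_event=(t == t0),
                    ))
    return pd.DataFrame(rows)


def spine_cv(values, min_sessions: int = 3) -> float:
    """Coefficient of variation: sample SD (n-1) over arithmetic mean.

    Returns NaN (and logs) when fewer than ``min_sessions`` valid values
    are available.
    """
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if len(v) < min_sessions:
        log.debug("spine_cv: only %d valid sessions (< %d)", len(v), min_sessions)
        return float("nan")
    m = v.mean()
    if m == 0:
        return float("nan")
    return float(v.std(ddof=1) / m)


def cv_table(rel_values: pd.DataFrame, window: tuple[str, ...] | None = None,
             col: str = "sglua1", min_sessions: int = 3) -> pd.DataFrame:
    """Per-spine CV of relative values over an optional session window."""
    df = rel_values
    if window is not None:
        df = df.loc[df["session"].isin(window)]
    rows = []
    for spine_id, sub in df.groupby("spine_id", sort=True):
        cv = spine_cv(sub[col], min_sessions=min_sessions)
        if np.isfinite(cv):
            rows.append(dict(
                spine_id=spine_id, dendrite_id=sub["dendrite_id"].iloc[0],
                cv=cv, n_sessions=int(sub[col].notna().sum()),
            ))
    return pd.DataFrame(rows)


def cross_day_correlation(values_a, values_b) -> tuple[float, float, int]:
    """Pearson correlation between paired per-spine levels on two days.

    Returns ``(r, p, n)`` over spines with valid values on both days.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired value vectors differ in length")
    ok = np.isfinite(a) & np.isfinite(b)
    if ok.sum() < 3:
        raise ValueError("need at least 3 paired spines")
    r, p = sps.pearsonr(a[ok], b[ok])
    return float(r), float(p), int(ok.sum())


def size_fluorescence_coupling(changes: pd.DataFrame,
                               sglua1_col: str = "sglua1",
                               size_col: str = "size",
                               min_transitions: int = 3,
                               inverse_r_threshold: float = 0.0) -> dict:
    """Coupling between daily spine-size change and daily sGluA1 change.

    ``changes`` is a long table of per-spine daily change ratios.
    Returns the pooled Pearson correlation over all spine-transitions,
    per-spine correlations (spines with ≥ ``min_transitions`` paired
    transitions), and the fraction of spines whose per-spine r falls
    below ``inverse_r_threshold`` (the "inverse-correlation" subset).
    """
    df = changes.dropna(subset=[sglua1_col, size_col])
    if len(df) < 3:
        raise ValueError("need at least 3 paired daily changes")
    pooled_r, pooled_p = sps.pearsonr(df[sglua1_col], df[size_col])

    per_spine = []
    for spine_id, sub in df.groupby("spine_id", sort=True):
        if len(sub) < min_transitions:
            continue
        if sub[sglua1_col].nunique() < 2 or sub[size_col].nunique() < 2:
            continue
        r, p = sps.pearsonr(sub[sglua1_col], sub[size_col])
        per_spine.append(dict(spine_id=spine_id, r=float(r), p=float(p),
                              n_transitions=len(sub)))
    per_spine = pd.DataFrame(per_spine)
    inverse_fraction = (
        float((per_spine["r"] < inverse_r_threshold).mean())
        if len(per_spine) else float("nan")
    )
    return dict(
        pooled_r=float(pooled_r), pooled_p=float(pooled_p),
        n_transitions=int(len(df)), per_spine=per_spine,
        inverse_fraction=inverse_fraction,
    )


def distribution_shift(group_a, group_b) -> dict:
    """Two-sample Kolmogorov–Smirnov comparison with shift direction.

    Returns the KS statistic, p-value and both medians so callers can
    report which way the distribution moved.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    a = a[np.isfinite(a)]
    b = b[np.isfinite(b)]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("both groups need at least 2 values")
    stat, p = sps.ks_2samp(a, b)
    return dict(
        statistic=float(stat), p_value=float(p),
        median_a=float(np.median(a)), median_b=float(np.median(b)),
        n_a=len(a), n_b=len(b),
    )
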