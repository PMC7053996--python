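"""Visual-deprivation analyses: baseline-normalized timecourses,
decrease / no-decrease response classification, basal-to-apical change
ratios, and depth / branch-distance coordinate analyses.

Conventions: z is depth below the pia in µm (increasing downward);
"relative depth" and "relative distance" are min–max scaled within a
dendrite (0 = most superficial / most proximal spine, 1 = deepest /
most distal); per-dendrite change summaries are geometric means over
persistent spines of baseline-normalized values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .schedules import Schedule
from .stats import StatResult, route_test

__all__ = [
    "ResponseClassification",
    "timecourse",
    "sham_threshold",
    "classify_response",
    "classification_summary",
    "day1_day7_correlation",
    "basal_apical_ratio",
    "relative_depth_on_dendrite",
    "relative_distance_on_dendrite",
    "dendrite_orientation",
    "dendrite_depth",
    "coordinate_correlation",
    "depth_extremes_change",
]

log = logging.getLogger(__name__)

#: printed fallback thresholds (sham-group SD of VD1 percent change)
PAPER_THRESHOLDS = {"dendrite": 0.18, "spine": 0.435, "cell": 0.098}


@dataclass(frozen=True)
class ResponseClassification:
    unit_id: str
    unit_level: str           # dendrite | spine | cell
    label: str                # decrease | no_decrease
    threshold: float
    session_evaluated: str
    value: float


def _summary_matrix(summaries: pd.DataFrame, schedule: Schedule) -> pd.DataFrame:
    """Pivot per-dendrite summaries to a (unit x session) matrix."""
    return (
        summaries.pivot(index="dendrite_id", columns="session", values="value")
        .reindex(columns=list(schedule.sessions))
    )


def timecourse(summaries: pd.DataFrame, schedule: Schedule,
               alpha: float = 0.05) -> tuple[pd.DataFrame, StatResult]:
    """Group timecourse of per-dendrite baseline-normalized change.

    ``summaries`` holds one geometric-mean value per dendrite x session
    (``dendrite_id, session, value``), already normalized to the
    baseline mean.  Dendrites with any missing session are excluded (and
    logged).  Returns the per-session mean ± SEM table and a
    repeated-measures test of session (post hoc: each post-deprivation
    session vs the pooled baseline).
    """
    mat = _summary_matrix(summaries, schedule)
    complete = mat.dropna()
    n_dropped = len(mat) - len(complete)
    if n_dropped:
        log.info("timecourse: excluded %d dendrites with incomplete sessions",
                 n_dropped)
    if len(complete) < 2:
        raise ValueError("need >= 2 dendrites with complete timecourses")
    table = pd.DataFrame({
        "session": list(schedule.sessions),
        "mean": complete.mean(axis=0).to_numpy(),
        "sem": complete.sem(axis=0).to_numpy(),
        "n": len(complete),
    })
    baseline_cols = tuple(schedule.index(s) for s in schedule.baseline)
    result = route_test(
        complete.to_numpy(), "repeated_oneway", alpha=alpha,
        labels=tuple(schedule.sessions), baseline_cols=baseline_cols,
    )
    return table, result


def sham_threshold(sham_values_at_vd1, warn_degenerate: bool = True) -> float:
    """Sample SD of the sham group's relative change at VD1.

    ``sham_values_at_vd1`` are baseline-normalized values (1 = no
    change); the threshold is the SD of ``value - 1`` as a positive
    fraction.  This is the data-driven counterpart of the printed
    constants (0.18 for dendrites, 0.435 for spines, 0.098 for cells).
    """
    x = np.asarray(sham_values_at_vd1, dtype=float)
    x = x[np.isfinite(x)]
    if len(x) < 3:
        raise ValueError("need >= 3 sham units to estimate the threshold")
    sd = float(np.std(x - 1.0, ddof=1))
    if sd == 0 and warn_degenerate:
        log.warning("sham_threshold: all sham changes identical; threshold 0")
    return sd


def classify_response(values_at_vd1: pd.Series, threshold: float,
                      unit_level: str = "dendrite",
                      session: str = "VD1") -> list[ResponseClassification]:
    """Label units decrease / no-decrease from their VD1 relative value.

    A unit is "decrease" when its baseline-normalized value at VD1 falls
    to ``1 - threshold`` or below; units with no valid VD1 value are
    excluded and logged.
    """
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    out = []
    n_excluded = 0
    for unit_id, v in values_at_vd1.items():
        if not np.isfinite(v):
            n_excluded += 1
            continue
        label = "decrease" if v <= 1.0 - threshold else "no_decrease"
        out.append(ResponseClassification(
            unit_id=str(unit_id), unit_level=unit_level, label=label,
            threshold=float(threshold), session_evaluated=session,
            value=float(v),
        ))
    if n_excluded:
        log.info("classify_response: excluded %d units without a valid %s "
                 "value", n_excluded, session)
    return out


def classification_summary(classifications: list[ResponseClassification]) -> dict:
    """Counts and percentage of decrease units."""
    n = len(classifications)
    if n == 0:
        raise ValueError("no classified units")
    n_dec = sum(c.label == "decrease" for c in classifications)
    return dict(
        n_decrease=n_dec, n_no_decrease=n - n_dec, n_total=n,
        percent_decrease=100.0 * n_dec / n,
    )


def day1_day7_correlation(changes_vd1, changes_vd7) -> tuple[float, float, int]:
    """Pearson correlation of per-unit relative changes at VD1 vs VD7."""
    a = np.asarray(changes_vd1, dtype=float)
    b = np.asarray(changes_vd7, dtype=float)
    if a.shape != b.shape:
        raise ValueError("change vectors differ in length")
    ok = np.isfinite(a) & np.isfinite(b)
    if ok.sum() < 3:
        raise ValueError("need >= 3 units with both sessions")
    r, p = sps.pearsonr(a[ok], b[ok])
    return float(r), float(p), int(ok.sum())


def basal_apical_ratio(summaries: pd.DataFrame, dendrites: pd.DataFrame,
                       session: str, eps: float = 0.05) -> pd.DataFrame:
    """Per-neuron ratio of basal over apical relative sGluA1 change.

    A neuron's dendrites are pooled by geometric mean per compartment
    first; neurons lacking either compartment at the session, or whose
    apical change is ``<= eps``, are excluded and logged.
    """
    meta = dendrites.set_index("dendrite_id")[["neuron_id", "compartment"]]
    df = summaries.loc[summaries["session"] == session].join(
        meta, on="dendrite_id")
    rows = []
    n_excluded = 0
    for neuron_id, sub in df.groupby("neuron_id", sort=True):
        by_comp = {}
        for comp, csub in sub.groupby("compartment"):
            vals = csub["value"].dropna()
            vals = vals[vals > 0]
            if len(vals):
                by_comp[comp] = float(sps.gmean(vals))
        if "apical" not in by_comp or "basal" not in by_comp:
            n_excluded += 1
            continue
        if by_comp["apical"] <= eps:
            n_excluded += 1
            continue
        rows.append(dict(
            neuron_id=neuron_id, session=session,
            apical=by_comp["apical"], basal=by_comp["basal"],
            ratio=by_comp["basal"] / by_comp["apical"],
        ))
    if n_excluded:
        log.info("basal_apical_ratio: excluded %d neurons at %s",
                 n_excluded, session)
    return pd.DataFrame(rows)


def _minmax(values: np.ndarray) -> np.ndarray:
    lo, hi = values.min(), values.max()
    if hi == lo:
        raise ValueError("all coordinates identical; relative scale undefined")
    return (values - lo) / (hi - lo)


def relative_depth_on_dendrite(z_um) -> np.ndarray:
    """Per-spine depth in [0, 1]: 0 = most superficial spine, 1 = deepest."""
    z = np.asarray(z_um, dtype=float)
    if len(z) < 2:
        raise ValueError("need >= 2 spines for a relative depth")
    return _minmax(z)


def relative_distance_on_dendrite(dist_um) -> np.ndarray:
    """Per-spine branch distance in [0, 1]: 0 = most proximal, 1 = most
    distal spine."""
    d = np.asarray(dist_um, dtype=float)
    if len(d) < 2:
        raise ValueError("need >= 2 spines for a relative distance")
    return _minmax(d)


def dendrite_orientation(prox_xyz, dist_xyz, min_slope: float = 0.1) -> str:
    """Classify a segment as ascending / descending / excluded.

    Ascending segments run toward the pia (distal end shallower than the
    proximal end); descending segments run away from it; segments with
    |Δdepth| / Δdistance at or below ``min_slope`` are excluded as
    effectively horizontal.
    """
    p = np.asarray(prox_xyz, dtype=float)
    d = np.asarray(dist_xyz, dtype=float)
    dz = d[2] - p[2]
    dist = float(np.linalg.norm(d - p))
    if dist == 0:
        raise ValueError("segment endpoints coincide")
    if abs(dz) / dist <= min_slope:
        return "excluded"
    return "ascending" if dz < 0 else "descending"


def dendrite_depth(spine_z_by_dendrite: dict[str, np.ndarray]) -> pd.DataFrame:
    """Mean spine depth per dendrite, min–max scaled within the imaging ROI.

    Relative depth is NaN when the ROI holds a single dendrite.
    """
    rows = [
        dict(dendrite_id=k, depth_um=float(np.mean(v)))
        for k, v in spine_z_by_dendrite.items()
        if len(np.atleast_1d(v)) >= 1
    ]
    out = pd.DataFrame(rows)
    if len(out) >= 2 and out["depth_um"].nunique() > 1:
        out["relative_depth"] = _minmax(out["depth_um"].to_numpy())
    else:
        out["relative_depth"] = np.nan
    return out


def coordinate_correlation(values, coordinates) -> tuple[float, float, int]:
    """Pearson correlation between a per-unit value and a coordinate.

    Used for change-at-VD7 vs relative depth / distance and for baseline
    level vs relative distance.
    """
    v = np.asarray(values, dtype=float)
    c = np.asarray(coordinates, dtype=float)
    if v.shape != c.shape:
        raise ValueError("value and coordinate vectors differ in length")
    ok = np.isfinite(v) & np.isfinite(c)
    if ok.sum() < 3:
        raise ValueError("need >= 3 units")
    r, p = sps.pearsonr(v[ok], c[ok])
    return float(r), float(p), int(ok.sum())


def _round_half_away(x: float) -> int:
    return int(np.floor(x + 0.5))


def depth_extremes_change(changes: pd.Series, z_um: pd.Series,
                          fraction: float = 0.15) -> tuple[float, float]:
    """Mean change of the deepest vs the most superficial spines.

    Groups hold ``k = max(1, round(fraction * n))`` spines each, taken by
    z rank along the same dendritic segment (ties broken by spine id for
    determinism).  Returns ``(deep_mean, superficial_mean)``.
    """
    df = pd.DataFrame({"change": changes, "z": z_um}).dropna()
    n = len(df)
    if n < int(np.ceil(1.0 / fraction)):
        raise ValueError(
            f"dendrite has {n} spines; need >= {int(np.ceil(1.0 / fraction))} "
            f"for {fraction:.0%} extremes"
        )
    k = max(1, _round_half_away(fraction * n))
    # stable sort on z after an index sort -> deterministic tie-breaking
    order = df.sort_index().sort_values("z", kind="mergesort")
    superficial = order.head(k)["change"].mean()
    deep = order.tail(k)["change"].mean()
    return float(deep), float(superficial)
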