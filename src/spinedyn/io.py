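"""Readers and writers for the long-format spine tables.

Tables are UTF-8 TSV with ``#``-prefixed header metadata lines (schema
version, units, schedule), '.' decimal separator and empty fields for
missing values.  A dataset on disk is a directory holding ``spines.tsv``
(one row per spine x session), ``dendrites.tsv`` (segment metadata) and
``sessions.tsv`` (schedule layout).  Optional rendered stacks are
multi-page TIFF plus a JSON sidecar of ROI pixel-run masks.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .quantify import RoiMaskSet
from .schedules import SCHEDULES, Schedule, get_schedule
from .synthgen import SyntheticConfig, SyntheticDataset

__all__ = [
    "SCHEMA_VERSION",
    "write_spine_table",
    "read_spine_table",
    "write_stack",
    "read_stack",
]

log = logging.getLogger(__name__)

SCHEMA_VERSION = "1"

SPINE_COLUMNS = [
    "spine_id", "dendrite_id", "neuron_id", "session", "present",
    "green_spine", "red_spine", "red_shaft",
    "bg_green_spine", "bg_red_spine", "bg_red_shaft",
    "x_um", "y_um", "z_um", "dist_branch_um",
]
DENDRITE_COLUMNS = [
    "dendrite_id", "neuron_id", "compartment", "layer", "region",
    "genotype", "condition",
    "prox_x_um", "prox_y_um", "prox_z_um",
    "dist_x_um", "dist_y_um", "dist_z_um",
]


def _write_tsv(df: pd.DataFrame, path: Path, header_lines: list[str]) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=False, na_rep="")


def _read_tsv(path: Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def write_spine_table(dataset: SyntheticDataset, out_dir: str | Path) -> Path:
    """Write a dataset directory (spines/dendrites/sessions TSVs)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sched = dataset.schedule
    head = [
        f"spinedyn spine table, schema version {SCHEMA_VERSION}",
        "coordinates in um; z = depth below pia; intensities in arbitrary units",
        f"schedule: {sched.name}",
    ]
    _write_tsv(dataset.spines[SPINE_COLUMNS], out / "spines.tsv", head)
    _write_tsv(dataset.dendrites[DENDRITE_COLUMNS], out / "dendrites.tsv",
               [f"spinedyn dendrite metadata, schema version {SCHEMA_VERSION}"])
    sessions = pd.DataFrame({
        "session": list(sched.sessions),
        "day": list(sched.days),
        "phase": ["baseline" if s in sched.baseline else "post"
                  for s in sched.sessions],
        "schedule": sched.name,
    })
    _write_tsv(sessions, out / "sessions.tsv",
               [f"spinedyn session layout, schema version {SCHEMA_VERSION}"])
    return out


def read_spine_table(path: str | Path) -> SyntheticDataset:
    """Read and validate a dataset directory written by write_spine_table.

    Checks the schema (column names), (spine_id, session) uniqueness and
    foreign-key integrity; raises with the offending column or row.
    """
    p = Path(path)
    spines = _read_tsv(p / "spines.tsv")
    dendrites = _read_tsv(p / "dendrites.tsv")
    sessions = _read_tsv(p / "sessions.tsv")

    missing = [c for c in SPINE_COLUMNS if c not in spines.columns]
    if missing:
        raise ValueError(f"spines.tsv schema mismatch: missing column(s) "
                         f"{', '.join(missing)}")
    missing = [c for c in DENDRITE_COLUMNS if c not in dendrites.columns]
    if missing:
        raise ValueError(f"dendrites.tsv schema mismatch: missing column(s) "
                         f"{', '.join(missing)}")
    if len(spines) == 0:
        raise ValueError("no spines in table")

    dup = spines.duplicated(subset=["spine_id", "session"])
    if dup.any():
        row = int(np.flatnonzero(dup.to_numpy())[0])
        raise ValueError(
            f"duplicate (spine_id, session) at spines.tsv data row {row}: "
            f"{spines.iloc[row]['spine_id']}/{spines.iloc[row]['session']}"
        )
    known_dend = set(dendrites["dendrite_id"])
    bad = ~spines["dendrite_id"].isin(known_dend)
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise ValueError(
            f"dangling dendrite_id {spines.iloc[row]['dendrite_id']!r} at "
            f"spines.tsv data row {row}"
        )

    sched_name = str(sessions["schedule"].iloc[0])
    if sched_name in SCHEDULES:
        sched = get_schedule(sched_name)
    else:
        sched = Schedule(
            name=sched_name,
            sessions=tuple(sessions["session"].astype(str)),
            days=tuple(int(d) for d in sessions["day"]),
            baseline=tuple(sessions.loc[sessions["phase"] == "baseline",
                                        "session"].astype(str)),
        )
    order = {s: i for i, s in enumerate(sched.sessions)}
    unknown = ~spines["session"].isin(order)
    if unknown.any():
        row = int(np.flatnonzero(unknown.to_numpy())[0])
        raise ValueError(f"unknown session {spines.iloc[row]['session']!r} "
                         f"at spines.tsv data row {row}")
    spines = spines.sort_values(
        ["spine_id", "session"], key=lambda s: s.map(order) if s.name == "session" else s
    ).reset_index(drop=True)
    spines["present"] = spines["present"].astype(bool)
    log.info("read %d spine rows, %d dendrites (%s schedule)",
             len(spines), len(dendrites), sched.name)

    cfg = SyntheticConfig(schedule=sched.name) if sched.name in SCHEDULES \
        else SyntheticConfig()
    return SyntheticDataset(config=cfg, schedule=sched, spines=spines,
                            dendrites=dendrites, truth={})


# ---------------------------------------------------------------------------
# TIFF stacks + JSON ROI-mask sidecar

def _mask_to_runs(mask: np.ndarray) -> list[list[int]]:
    runs = []
    for z, y in zip(*np.nonzero(mask.any(axis=2))):
        xs = np.flatnonzero(mask[z, y])
        start = xs[0]
        prev = xs[0]
        for x in xs[1:]:
            if x != prev + 1:
                runs.append([int(z), int(y), int(start), int(prev) + 1])
                start = x
            prev = x
        runs.append([int(z), int(y), int(start), int(prev) + 1])
    return runs


def _runs_to_mask(runs, shape) -> np.ndarray:
    mask = np.zeros(shape, dtype=bool)
    for z, y, x0, x1 in runs:
        mask[z, y, x0:x1] = True
    return mask


def write_stack(stack: np.ndarray, masks: RoiMaskSet, path: str | Path) -> Path:
    """Write a (z, 2, y, x) stack as multi-page TIFF + JSON mask sidecar."""
    import tifffile

    path = Path(path)
    tifffile.imwrite(path, stack.astype(np.float32), imagej=True,
                     metadata={"axes": "ZCYX"})
    sidecar = {
        "shape": list(masks.shape),
        "rois": {name: _mask_to_runs(m) for name, m in masks.masks.items()},
    }
    with open(path.with_suffix(".rois.json"), "w", encoding="utf-8") as fh:
        json.dump(sidecar, fh)
    return path


def read_stack(path: str | Path) -> tuple[np.ndarray, RoiMaskSet]:
    import tifffile

    path = Path(path)
    stack = np.asarray(tifffile.imread(path), dtype=float)
    if stack.ndim == 3:  # single-z collapsed by the writer
        stack = stack[None]
    with open(path.with_suffix(".rois.json"), encoding="utf-8") as fh:
        sidecar = json.load(fh)
    shape = tuple(sidecar["shape"])
    masks = {name: _runs_to_mask(runs, shape)
             for name, runs in sidecar["rois"].items()}
    return stack, RoiMaskSet(shape=shape, masks=masks)
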