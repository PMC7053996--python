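"""Render a simulated dendrite as a small two-channel 3D image stack.

The dendritic shaft is drawn as a bright tube in the red channel; each
present spine becomes a Gaussian blob in both channels scaled so the mean
pixel value over its ROI mask equals the simulated raw ROI intensity
(minus the background field that fills the rest of the stack).  The
emitted masks satisfy the ROI contract of
:func:`spinedyn.quantify.extract_roi_intensities`, so rendering followed
by extraction round-trips the simulated raw values up to discretization.
"""

from __future__ import annotations

import numpy as np

from .quantify import RoiMaskSet
from .synthgen import SyntheticDataset

__all__ = ["render_session_stack"]


def _disk_mask(shape, zc, yc, xc, r_xy=3, r_z=1) -> np.ndarray:
    zz, yy, xx = np.ogrid[:shape[0], :shape[1], :shape[2]]
    return (((yy - yc) ** 2 + (xx - xc) ** 2) <= r_xy**2) & (
        np.abs(zz - zc) <= r_z)


def _paint_blob(img, mask, zc, yc, xc, target_mean, sigma=1.6):
    """Add a Gaussian blob whose mean over ``mask`` equals ``target_mean``."""
    zz, yy, xx = np.indices(img.shape)
    blob = np.exp(
        -(((yy - yc) ** 2 + (xx - xc) ** 2) / (2 * sigma**2)
          + (zz - zc) ** 2 / (2 * 1.0**2))
    )
    mean_in_mask = blob[mask].mean()
    if mean_in_mask > 0:
        img += blob * (target_mean / mean_in_mask)


def render_session_stack(dataset: SyntheticDataset, dendrite_id: str,
                         session: str, shape: tuple[int, int, int] = (16, 256, 256),
                         ) -> tuple[np.ndarray, RoiMaskSet]:
    """Render one dendrite at one session.

    Returns ``(stack, masks)`` with stack shape (z, 2, y, x): channel 0
    green (SEP-GluA1), channel 1 red (dsRed2).  Raises for unknown
    dendrite or session.
    """
    if dendrite_id not in set(dataset.dendrites["dendrite_id"]):
        raise KeyError(f"unknown dendrite {dendrite_id!r}")
    if session not in dataset.schedule.sessions:
        raise KeyError(f"session {session!r} not in schedule "
                       f"{dataset.schedule.name!r}")
    rows = dataset.spines.query(
        "dendrite_id == @dendrite_id and session == @session and present"
    ).reset_index(drop=True)
    if len(rows) == 0:
        raise ValueError(f"no present spines on {dendrite_id} at {session}")

    nz, ny, nx = shape
    green = np.zeros((nz, ny, nx))
    red = np.zeros((nz, ny, nx))

    # lay the shaft along x at mid-height, spines spread by branch distance
    shaft_y, shaft_z = ny // 2, nz // 2
    bg_mean = float(np.nanmean(
        rows[["bg_green_spine", "bg_red_spine", "bg_red_shaft"]].to_numpy()))
    green += bg_mean
    red += bg_mean

    # spines laid out in branch-distance order at uniform pixel spacing so
    # neighbouring blobs and masks never overlap
    order = rows["dist_branch_um"].rank(method="first").to_numpy() - 1
    denom = max(1.0, float(len(rows) - 1))
    x_pos = 20 + order / denom * (nx - 40)

    masks: dict[str, np.ndarray] = {}
    shaft_mask = np.zeros(shape, dtype=bool)
    shaft_mask[shaft_z - 1:shaft_z + 2, shaft_y - 2:shaft_y + 3, 10:nx - 10] = True
    shaft_val = float(rows["red_shaft"].mean())
    red[shaft_mask] += shaft_val - bg_mean
    masks["shaft"] = shaft_mask

    spine_offset = 12  # pixels above the shaft
    for i, row in rows.iterrows():
        yc = shaft_y - spine_offset
        xc = int(round(x_pos[i]))
        zc = shaft_z
        m = _disk_mask(shape, zc, yc, xc)
        g_amp = row["green_spine"] - bg_mean
        r_amp = row["red_spine"] - bg_mean
        if g_amp > 0:
            _paint_blob(green, m, zc, yc, xc, g_amp)
        if r_amp > 0:
            _paint_blob(red, m, zc, yc, xc, r_amp)
        masks[f"spine/{row['spine_id']}"] = m
        bg_m = _disk_mask(shape, zc, max(4, yc - 30), xc)
        masks[f"bg/{row['spine_id']}"] = bg_m
    masks["bg/shaft"] = np.roll(shaft_mask, ny // 3, axis=1)

    stack = np.stack([green, red], axis=1)
    return stack, RoiMaskSet(shape=shape, masks=masks)
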