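"""Mask pipeline: reference frame, background threshold, zone partition, ROI traces.

One plant mask is built from a single high-contrast reference frame (by
default the frame nearest 180 min, when cotyledon fluorescence is near
maximal) and applied unchanged to every round of the protocol; seedling
movement over the 4 h is assumed negligible. The mask is partitioned per grid
cell into three horizontal bands — cotyledons on top, hypocotyls in the
middle, roots at the bottom — matching the vertical cultivation orientation.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage.filters import threshold_otsu

from chlorokin.errors import (
    AlignmentError,
    ConfigError,
    DegenerateInputError,
    NoValidFrameError,
)
from chlorokin.synthgen import ZONE_CODES, ZONES, FrameStack, PlateLayout

logger = logging.getLogger(__name__)

_ZONE_NAME = {v: k for k, v in ZONE_CODES.items()}

DEFAULT_BAND_FRACTIONS = (0.25, 0.45, 0.30)


@dataclass
class PlantMask:
    """Plant-pixel mask with zone and grid-cell labels.

    ``zone_labels`` uses the shared zone codes (0 = none); ``cell_labels``
    holds 1-based grid-cell ids (0 = none). Labels are only assigned where
    ``plant_pixels`` is true.
    """

    plant_pixels: np.ndarray
    zone_labels: np.ndarray
    cell_labels: np.ndarray
    reference_frame_index: int
    threshold_used: float


def select_reference_frame(
    stack: FrameStack,
    saturation_fraction_max: float = 0.001,
    target_time_min: float | None = 180.0,
) -> int:
    """Pick the mask reference frame.

    A frame qualifies if its saturated-pixel fraction is at most
    ``saturation_fraction_max``. With a ``target_time_min`` configured
    (default 180 min), the qualifying frame nearest that time is returned;
    otherwise (``target_time_min=None``, auto mode) the qualifying frame with
    the highest contrast (intensity SD) wins, earliest index on ties.
    """
    if stack.n_rounds < 1:
        raise NoValidFrameError("empty stack")
    n_pix = stack.data.shape[1] * stack.data.shape[2]
    sat_frac = (stack.data >= stack.saturation_value).reshape(stack.n_rounds, -1).sum(axis=1) / n_pix
    ok = sat_frac <= saturation_fraction_max
    if not ok.any():
        raise NoValidFrameError(
            f"all {stack.n_rounds} frames exceed the saturation limit {saturation_fraction_max}"
        )
    if target_time_min is not None:
        order = np.argsort(np.abs(stack.timestamps_min - target_time_min), kind="stable")
        for idx in order:
            if ok[idx]:
                return int(idx)
    sd = stack.data.reshape(stack.n_rounds, -1).std(axis=1)
    sd[~ok] = -np.inf
    return int(np.argmax(sd))  # argmax returns the earliest maximizer


def threshold_mask(
    frame: np.ndarray,
    method: str = "otsu",
    manual_threshold: float | None = None,
) -> tuple[np.ndarray, float]:
    """Background subtraction by intensity threshold.

    Returns ``(mask, threshold)`` where a pixel is plant iff its intensity is
    strictly above the threshold. ``method='otsu'`` (default) is
    parameter-free: a plain two-class Otsu split lands between the tissue
    intensity tiers (root ≪ hypocotyl < cotyledon) rather than at the
    background, so the cut is refined iteratively — the sub-threshold pixels
    are re-split with Otsu's criterion and the lower cut adopted as long as
    the split is clearly bimodal (median separation exceeding twice the
    summed robust within-class scales, MAD-based so a few stray pixels from
    a brighter tier cannot mask the valley); pure background noise fails
    that test, so the recursion stops at the background/root boundary.
    ``method='fixed'`` replays an explicit threshold.
    """
    frame = np.asarray(frame)
    if frame.ndim != 2:
        raise AlignmentError(f"expected a 2-D frame, got shape {frame.shape}")
    if method == "fixed":
        if manual_threshold is None:
            raise ConfigError("method='fixed' requires manual_threshold")
        thr = float(manual_threshold)
    elif method == "otsu":
        if frame.max() == frame.min():
            raise DegenerateInputError("constant frame: Otsu threshold undefined")
        thr = float(threshold_otsu(frame))
        for _ in range(4):  # at most: cotyledon | hypocotyl | root | background
            low = frame[frame <= thr].astype(np.float64)
            if low.size < 2 or low.max() == low.min():
                break
            thr_low = float(threshold_otsu(low))
            a, b = low[low <= thr_low], low[low > thr_low]
            if not (a.size and b.size):
                break
            scale = 1.4826 * (
                np.median(np.abs(a - np.median(a))) + np.median(np.abs(b - np.median(b)))
            )
            if np.median(b) - np.median(a) <= 2.0 * scale:
                break
            thr = thr_low
    else:
        raise ConfigError(f"unknown threshold method {method!r}")
    return frame > thr, thr


def partition_zones(
    plant_pixels: np.ndarray,
    layout: PlateLayout,
    band_fractions: tuple[float, float, float] = DEFAULT_BAND_FRACTIONS,
) -> tuple[np.ndarray, np.ndarray]:
    """Split the plant mask of each grid cell into cotyledon/hypocotyl/root bands.

    Within each cell the occupied row extent of the mask is divided top-down
    by ``band_fractions`` (cotyledon/hypocotyl/root). Every plant pixel gets
    exactly one zone and one cell; plant pixels outside any grid cell are
    labeled cell 0 / zone 0 with a logged warning.
    """
    if abs(sum(band_fractions) - 1.0) > 1e-9:
        raise ConfigError(f"band fractions must sum to 1, got {band_fractions}")
    h, w = plant_pixels.shape
    zone_labels = np.zeros((h, w), dtype=np.uint8)
    cell_labels = np.zeros((h, w), dtype=np.int32)
    covered = np.zeros((h, w), dtype=bool)
    rects = layout.cell_pixel_rects((h, w))
    rows_idx = np.arange(h)[:, None]
    for cell_id, (r0, r1, c0, c1) in rects.items():
        sub = plant_pixels[r0:r1, c0:c1]
        covered[r0:r1, c0:c1] = True
        if not sub.any():
            continue
        occ_rows = np.nonzero(sub.any(axis=1))[0]
        top, bot = occ_rows[0], occ_rows[-1] + 1
        extent = bot - top
        cot_end = top + int(np.ceil(band_fractions[0] * extent))
        hyp_end = cot_end + int(np.round(band_fractions[1] * extent))
        hyp_end = min(max(hyp_end, cot_end), bot)
        sub_rows = np.arange(r0, r1)[:, None] - r0
        zone_sub = np.where(
            sub_rows < cot_end,
            ZONE_CODES["cotyledon"],
            np.where(sub_rows < hyp_end, ZONE_CODES["hypocotyl"], ZONE_CODES["root"]),
        ).astype(np.uint8)
        zone_labels[r0:r1, c0:c1][sub] = np.broadcast_to(zone_sub, sub.shape)[sub]
        cell_labels[r0:r1, c0:c1][sub] = cell_id
    stray = plant_pixels & ~covered
    if stray.any():
        logger.warning("%d plant pixels fall outside all grid cells; labeled none", stray.sum())
    return zone_labels, cell_labels


def build_mask(
    stack: FrameStack,
    layout: PlateLayout,
    method: str = "otsu",
    manual_threshold: float | None = None,
    saturation_fraction_max: float = 0.001,
    target_time_min: float | None = 180.0,
    band_fractions: tuple[float, float, float] = DEFAULT_BAND_FRACTIONS,
) -> PlantMask:
    """Full mask pipeline: reference frame → threshold → zone/cell partition."""
    ref = select_reference_frame(stack, saturation_fraction_max, target_time_min)
    plant, thr = threshold_mask(stack.data[ref], method=method, manual_threshold=manual_threshold)
    zones, cells = partition_zones(plant, layout, band_fractions)
    return PlantMask(
        plant_pixels=plant,
        zone_labels=zones,
        cell_labels=cells,
        reference_frame_index=ref,
        threshold_used=thr,
    )


def extract_traces(
    stack: FrameStack,
    mask: PlantMask,
    grouping: str = "cell_zone",
) -> pd.DataFrame:
    """Per-ROI mean/SD fluorescence for every round, fixed mask throughout.

    ``grouping='cell_zone'`` yields one ROI per (grid cell, zone);
    ``grouping='zone'`` pools all cells per zone. Returns a long-format
    DataFrame with columns ``cell, zone, round, time_min, n_pixels, mean, sd``
    (``cell`` is NA for zone grouping). ROIs with zero pixels yield NaN, not
    zero. SD is the population SD of the pixels in the ROI.
    """
    if stack.frame_shape != mask.plant_pixels.shape:
        raise AlignmentError(
            f"stack frames {stack.frame_shape} vs mask {mask.plant_pixels.shape}"
        )
    if grouping not in ("zone", "cell_zone"):
        raise ConfigError(f"unknown grouping {grouping!r}")

    zone = mask.zone_labels
    cell = mask.cell_labels
    valid = mask.plant_pixels & (zone > 0) & (cell > 0)
    if grouping == "zone":
        roi_of_pixel = zone[valid].astype(np.int64)
        n_rois = 4  # slots are zone codes 1..3, slot 0 unused
        iter_rois = [((pd.NA, _ZONE_NAME[z]), z) for z in range(1, 4)]
    else:
        max_cell = int(cell.max()) if cell.size else 0
        roi_of_pixel = (cell[valid].astype(np.int64) - 1) * 3 + (zone[valid].astype(np.int64) - 1)
        n_rois = max(max_cell * 3, 1)
        iter_rois = [
            ((c, _ZONE_NAME[z]), (c - 1) * 3 + (z - 1))
            for c in range(1, max_cell + 1)
            for z in range(1, 4)
        ]

    counts = np.bincount(roi_of_pixel, minlength=n_rois)
    flat = stack.data.reshape(stack.n_rounds, -1)[:, valid.ravel()].astype(np.float64)
    sums = np.vstack([np.bincount(roi_of_pixel, weights=row, minlength=n_rois) for row in flat])
    sumsq = np.vstack(
        [np.bincount(roi_of_pixel, weights=row**2, minlength=n_rois) for row in flat]
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        means = sums / counts
        var = np.clip(sumsq / counts - means**2, 0.0, None)
        sds = np.sqrt(var)

    records = []
    for (c, zname), slot in iter_rois:
        if grouping == "cell_zone" and counts[slot] == 0 and c not in mask.cell_labels:
            continue  # cell never present in the mask at all
        records.append(
            pd.DataFrame(
                {
                    "cell": c,
                    "zone": zname,
                    "round": np.arange(stack.n_rounds),
                    "time_min": stack.timestamps_min,
                    "n_pixels": counts[slot],
                    "mean": means[:, slot] if counts[slot] > 0 else np.nan,
                    "sd": sds[:, slot] if counts[slot] > 0 else np.nan,
                }
            )
        )
    out = pd.concat(records, ignore_index=True)
    return out
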