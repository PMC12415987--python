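"""Nucleus and cell segmentation.

Replaces the manual ImageJ workflow: nuclei from the DAPI channel by
smoothing, Otsu (or fixed) thresholding, hole filling and an optional
distance-transform watershed split; cell bodies from the CELLBODY channel as
connected foreground components seeded by nuclei, so that several nuclei
inside one unbroken cell body remain a single (multinucleated) cell.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage.filters import gaussian, threshold_otsu
from skimage.feature import peak_local_max
from skimage.measure import label as cc_label
from skimage.morphology import dilation, disk
from skimage.segmentation import clear_border, relabel_sequential, watershed


@dataclass(frozen=True)
class SegmentationParams:
    smooth_sigma_px: float = 2.0
    threshold_method: str = "otsu"  # or "fixed"
    fixed_threshold: float = 0.0
    min_nucleus_area_px: int = 50
    split_touching: bool = True
    watershed_min_distance_px: int = 7
    exclude_border: bool = True

    def __post_init__(self) -> None:
        if self.smooth_sigma_px < 0:
            raise ValueError("smooth_sigma_px must be non-negative")
        if self.threshold_method not in ("otsu", "fixed"):
            raise ValueError("threshold_method must be 'otsu' or 'fixed'")
        if self.min_nucleus_area_px < 1:
            raise ValueError("min_nucleus_area_px must be >= 1")
        if self.watershed_min_distance_px < 1:
            raise ValueError("watershed_min_distance_px must be >= 1")


def _foreground(image: np.ndarray, params: SegmentationParams) -> np.ndarray:
    smoothed = gaussian(image, sigma=params.smooth_sigma_px, preserve_range=True) \
        if params.smooth_sigma_px > 0 else image
    if params.threshold_method == "otsu":
        if np.ptp(smoothed) == 0:
            return np.zeros(image.shape, dtype=bool)
        thr = threshold_otsu(smoothed)
    else:
        thr = params.fixed_threshold
    return smoothed > thr


def segment_nuclei(dapi_2d: np.ndarray, params: SegmentationParams | None = None
                   ) -> np.ndarray:
    """Label nuclei in a 2D DAPI image; labels are compact 1..N.

    An all-background image yields an empty label map (not an error).
    """
    if params is None:
        params = SegmentationParams()
    dapi_2d = np.asarray(dapi_2d, dtype=float)
    if dapi_2d.ndim != 2:
        raise ValueError("segment_nuclei expects a 2D image")

    fg = _foreground(dapi_2d, params)
    fg = ndi.binary_fill_holes(fg)

    if params.split_touching:
        labels = _watershed_split(fg, params)
    else:
        labels = cc_label(fg, connectivity=2)

    sizes = np.bincount(labels.ravel())
    too_small = sizes < params.min_nucleus_area_px
    too_small[0] = False
    labels[too_small[labels]] = 0
    if params.exclude_border:
        labels = clear_border(labels)
    labels, _, _ = relabel_sequential(labels)
    return labels.astype(np.int32)


def _watershed_split(fg: np.ndarray, params: SegmentationParams) -> np.ndarray:
    if not fg.any():
        return np.zeros(fg.shape, dtype=np.int32)
    distance = ndi.distance_transform_edt(fg)
    # Smoothing the EDT collapses the ridge-shaped maximum of a single convex
    # nucleus to one peak while keeping two merged nuclei as two peaks.
    smooth_dist = ndi.gaussian_filter(distance, sigma=2.0)
    coords = peak_local_max(
        smooth_dist,
        min_distance=params.watershed_min_distance_px,
        labels=cc_label(fg, connectivity=2),
        exclude_border=False,
    )
    markers = np.zeros(fg.shape, dtype=np.int32)
    markers[tuple(coords.T)] = np.arange(1, len(coords) + 1)
    return watershed(-distance, markers, mask=fg, connectivity=2)


def segment_cells(cellbody_2d: np.ndarray, nuclei: np.ndarray,
                  params: SegmentationParams | None = None):
    """Delineate cells from the cell-body channel, anchored on nuclei.

    Each connected cell-body foreground component containing one or more
    nuclei becomes exactly one cell, so multinucleated cells remain single
    cells.  A nucleus falling outside all cell-body foreground becomes a
    one-nucleus cell equal to its own 10-px dilation and is flagged.

    Returns ``(cell_labels, fallback_cell_ids)``.
    """
    if params is None:
        params = SegmentationParams()
    cellbody_2d = np.asarray(cellbody_2d, dtype=float)
    if cellbody_2d.shape != nuclei.shape:
        raise ValueError("cell-body image and nuclei map must be aligned")

    fg = _foreground(cellbody_2d, params)
    fg = ndi.binary_fill_holes(fg)
    comp = cc_label(fg, connectivity=2)

    cell_labels = np.zeros(nuclei.shape, dtype=np.int32)
    fallback_ids: list[int] = []
    next_cell = 0
    comp_to_cell: dict[int, int] = {}

    nucleus_ids = np.unique(nuclei)
    nucleus_ids = nucleus_ids[nucleus_ids > 0]
    for nid in nucleus_ids:
        mask = nuclei == nid
        overlap = comp[mask]
        overlap = overlap[overlap > 0]
        if overlap.size:
            cid_comp = int(np.bincount(overlap).argmax())
            if cid_comp not in comp_to_cell:
                next_cell += 1
                comp_to_cell[cid_comp] = next_cell
                cell_labels[comp == cid_comp] = next_cell
        else:
            next_cell += 1
            dil = dilation(mask, footprint=disk(10))
            cell_labels[dil & (cell_labels == 0)] = next_cell
            fallback_ids.append(next_cell)

    # ensure every nucleus pixel belongs to its cell even if the body
    # threshold clipped it
    for nid in nucleus_ids:
        mask = nuclei == nid
        vals = cell_labels[mask]
        vals = vals[vals > 0]
        if vals.size:
            cid = int(np.bincount(vals).argmax())
            cell_labels[mask] = cid
    return cell_labels, fallback_ids


def assign_nuclei_to_cells(nuclei: np.ndarray, cells: np.ndarray
                           ) -> dict[int, list[int]]:
    """Map cell_id -> nucleus_id list by majority pixel overlap.

    Every nucleus is assigned; a nucleus with zero overlap with any cell maps
    to cell 0 (caller handles/flags it via :func:`segment_cells` fallback).
    """
    if nuclei.shape != cells.shape:
        raise ValueError("label maps must be aligned")
    mapping: dict[int, list[int]] = {}
    nucleus_ids = np.unique(nuclei)
    for nid in nucleus_ids[nucleus_ids > 0]:
        overlap = cells[nuclei == nid]
        pos = overlap[overlap > 0]
        cid = int(np.bincount(pos).argmax()) if pos.size else 0
        mapping.setdefault(cid, []).append(int(nid))
    return mapping
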