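"""Marker-intensity read-outs.

Implements the cytosolic-signal formula

    cytosolic intensity = (ID_cell - ID_nucleus) / (Area_cell - Area_nucleus)

where ID is integrated density (sum of pixel intensities over a region) —
i.e. the mean marker intensity over the cytosol ring — and, on top of it, the
nuclear-to-cytosolic intensity ratio used to score NF-κB p65 translocation,
Laplacian-of-Gaussian focus counting for γH2AX, and the proportion of
positive cells.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.morphology import dilation, disk, erosion, h_maxima


def integrated_density(image: np.ndarray, mask: np.ndarray) -> float:
    """Sum of pixel intensities over a region (area x mean intensity)."""
    return float(np.asarray(image, dtype=float)[np.asarray(mask, dtype=bool)].sum())


def _check_masks(marker, cell_mask, nucleus_mask):
    marker = np.asarray(marker, dtype=float)
    cell_mask = np.asarray(cell_mask, dtype=bool)
    nucleus_mask = np.asarray(nucleus_mask, dtype=bool)
    if marker.shape != cell_mask.shape or marker.shape != nucleus_mask.shape:
        raise ValueError("image and masks must share a shape")
    return marker, cell_mask, nucleus_mask


def cytosolic_intensity(marker_2d, cell_mask, nucleus_mask,
                        mode: str = "whole_cell") -> float:
    """Mean marker intensity over the cytosol.

    ``mode='whole_cell'`` (default) reads the first region as the whole cell
    and applies the subtraction formula
    ``(ID_cell - ID_nucleus) / (Area_cell - Area_nucleus)``; the nucleus must
    nest inside the cell and the cytosol must be non-empty.
    ``mode='strict'`` reads ``cell_mask`` as an already-cytosolic region and
    averages over ``cell_mask & ~nucleus_mask`` with no subtraction.
    """
    marker, cell_mask, nucleus_mask = _check_masks(marker_2d, cell_mask, nucleus_mask)
    if mode == "strict":
        cyto = cell_mask & ~nucleus_mask
        if not cyto.any():
            raise ValueError("empty cytosol")
        return float(marker[cyto].mean())
    if mode != "whole_cell":
        raise ValueError(f"unknown cytosol mode {mode!r}")
    if np.any(nucleus_mask & ~cell_mask):
        raise ValueError("nucleus mask must nest inside the cell mask")
    area_cell = int(cell_mask.sum())
    area_nuc = int(nucleus_mask.sum())
    if area_cell <= area_nuc:
        raise ValueError("empty cytosol: cell area must exceed nucleus area")
    id_cell = integrated_density(marker, cell_mask)
    id_nuc = integrated_density(marker, nucleus_mask)
    return (id_cell - id_nuc) / (area_cell - area_nuc)


def nuclear_cytosolic_ratio(marker_2d, cell_mask, nucleus_mask,
                            mode: str = "whole_cell") -> float:
    """Nuclear mean intensity / cytosolic intensity; NaN when the cytosolic
    intensity is zero (flagged undefined, excluded from group means)."""
    marker, cell_mask, nucleus_mask = _check_masks(marker_2d, cell_mask, nucleus_mask)
    if not nucleus_mask.any():
        raise ValueError("empty nucleus mask")
    cyto = cytosolic_intensity(marker, cell_mask, nucleus_mask, mode=mode)
    if cyto <= 0:
        return float("nan")
    nuclear_mean = float(marker[nucleus_mask].mean())
    return nuclear_mean / cyto


def annulus_cell_mask(nucleus_mask: np.ndarray, all_nuclei: np.ndarray | None = None,
                      dilation_px: int = 10) -> np.ndarray:
    """Fallback whole-cell region when no cell-body channel exists: the
    nucleus dilated by ``dilation_px``, clipped at image borders and at
    neighbouring nuclei."""
    nucleus_mask = np.asarray(nucleus_mask, dtype=bool)
    region = dilation(nucleus_mask, footprint=disk(dilation_px))
    if all_nuclei is not None:
        others = (np.asarray(all_nuclei) > 0) & ~nucleus_mask
        region &= ~others
    return region


@dataclass(frozen=True)
class FociParams:
    """Spot-detection parameters for diffraction-limited foci."""

    log_sigma_px: float = 2.0
    prominence_k: float = 5.0  # threshold in robust-SD units above background
    min_separation_px: int = 3

    def __post_init__(self) -> None:
        if self.log_sigma_px <= 0 or self.prominence_k <= 0:
            raise ValueError("log_sigma_px and prominence_k must be positive")
        if self.min_separation_px < 1:
            raise ValueError("min_separation_px must be >= 1")


# 3x3 second-difference kernel: responds to pixel-scale noise, nearly blind
# to structure smoother than ~2 px (diffraction-limited foci included)
_LAP3 = np.array([[1.0, -2.0, 1.0], [-2.0, 4.0, -2.0], [1.0, -2.0, 1.0]])
# E|N(0,1)| median is 0.6745 sigma; the kernel's own L2 norm is 6
_HALF_NORMAL_MEDIAN = 0.6745


def _log_filter_l2(sigma: float) -> float:
    """L2 norm of the scale-normalised LoG kernel (white-noise gain)."""
    half = int(np.ceil(4 * sigma))
    impulse = np.zeros((2 * half + 1, 2 * half + 1))
    impulse[half, half] = 1.0
    h = -(sigma**2) * ndi.gaussian_laplace(impulse, sigma=sigma)
    return float(np.sqrt((h**2).sum()))


def detect_foci(marker_2d: np.ndarray, nuclei: np.ndarray,
                params: FociParams | None = None,
                mapping: dict[int, list[int]] | None = None):
    """Count diffraction-limited foci per nucleus (and per cell).

    Band-pass by a scale-normalised Laplacian of Gaussian, then per nucleus:
    maxima of the response with topographic prominence of at least
    ``prominence_k`` robust SDs of the background response (h-maxima, which
    rejects ghost maxima formed where the skirts of clustered foci overlap)
    and absolute response above ``median + prominence_k * robust SD``;
    maxima closer than ``min_separation_px`` are suppressed in favour of the
    stronger.  The background response SD is obtained by estimating the
    nucleus's camera noise with a median-based second-difference estimator
    (insensitive to smooth structure, foci included) and propagating it
    through the LoG filter's L2 norm; the per-nucleus median keeps the
    threshold insensitive to intensity offsets.  Peaks are searched inside
    the nucleus eroded by a thin band so the band-pass edge response at the
    nuclear boundary cannot register as a focus.

    Returns ``(per_nucleus, per_cell)``: a Series of counts indexed by
    nucleus_id, and a Series indexed by cell_id when ``mapping`` is given
    (else ``None``).
    """
    if params is None:
        params = FociParams()
    marker = np.asarray(marker_2d, dtype=float)
    nuclei = np.asarray(nuclei)
    if marker.shape != nuclei.shape:
        raise ValueError("marker image and nuclei map must be aligned")

    sigma = params.log_sigma_px
    response = -(sigma**2) * ndi.gaussian_laplace(marker, sigma=sigma)
    second_diff = ndi.convolve(marker, _LAP3)
    noise_gain = _log_filter_l2(sigma)

    band = int(np.ceil(2.0 * sigma)) + 1
    interior = erosion(nuclei > 0, footprint=disk(band))
    search_labels = np.where(interior, nuclei, 0)

    nucleus_ids = np.unique(nuclei)
    nucleus_ids = nucleus_ids[nucleus_ids > 0]
    counts = pd.Series(0, index=pd.Index(nucleus_ids, name="nucleus_id"),
                       dtype=int, name="foci_count")

    if search_labels.any():
        boxes = ndi.find_objects(search_labels)
        for nid in nucleus_ids:
            if nid > len(boxes) or boxes[nid - 1] is None:
                continue
            sl = boxes[nid - 1]
            region = search_labels[sl] == nid
            sub = response[sl].copy()
            sub[~region] = sub[region].min()

            full = nuclei == nid
            noise_sd = float(np.median(np.abs(second_diff[full]))) \
                / (_HALF_NORMAL_MEDIAN * 6.0)
            # floor keeps noise-free images from promoting float-rounding
            # ripples on smooth response surfaces into maxima
            floor = 1e-6 * float(np.ptp(sub[region])) + 1e-9
            height = max(params.prominence_k * noise_sd * noise_gain, floor)
            thr = float(np.median(response[full])) + height

            prominent = h_maxima(sub, height)
            blobs, n_blobs = ndi.label(prominent)
            cands = []
            for b in range(1, n_blobs + 1):
                bmask = (blobs == b) & region
                if not bmask.any():
                    continue
                flat_idx = int(np.argmax(np.where(bmask, sub, -np.inf)))
                y, x = np.unravel_index(flat_idx, sub.shape)
                val = float(sub[y, x])
                if val > thr:
                    cands.append((val, int(y), int(x)))
            # greedy suppression: the stronger peak wins within min_separation
            cands.sort(reverse=True)
            kept: list[tuple[float, int, int]] = []
            for val, y, x in cands:
                if all((y - ky) ** 2 + (x - kx) ** 2
                       >= params.min_separation_px**2
                       for _, ky, kx in kept):
                    kept.append((val, y, x))
            counts.loc[nid] = len(kept)

    per_cell = None
    if mapping is not None:
        per_cell = pd.Series(
            {cid: int(counts.reindex(nids).fillna(0).sum())
             for cid, nids in mapping.items()},
            name="foci_count",
        )
        per_cell.index.name = "cell_id"
    return counts, per_cell


def positive_fraction(values, cutoff: float) -> float:
    """Fraction of values strictly greater than the cutoff (the proportion of
    marker-positive cells)."""
    values = np.asarray(list(values), dtype=float)
    if values.size == 0:
        raise ValueError("positive_fraction requires a non-empty value list")
    if not np.isfinite(cutoff):
        raise ValueError("cutoff must be finite")
    return float(np.mean(values > cutoff))
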