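"""Nuclear morphometry and the vehicle-referenced giant/MNC classifier.

The classifier follows the study's outlier convention: a cell is *giant* when
its total nuclear area or total nuclear perimeter (summed over all nuclei in
the cell) exceeds the vehicle-population mean by more than three standard
deviations; a cell is *multinucleated* when it contains more than one
nucleus.  The vehicle (untreated control) arm anchors the thresholds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage.measure import regionprops_table

NUCLEUS_COLUMNS = [
    "nucleus_id", "cell_id", "centroid_y", "centroid_x",
    "area_px2", "area_um2", "perimeter_px", "perimeter_um",
    "mean_dapi", "border_censored",
]

CELL_COLUMNS = [
    "cell_id", "n_nuclei", "nucleus_ids",
    "total_area_px2", "total_area_um2",
    "total_perimeter_px", "total_perimeter_um",
    "is_mnc", "flagged",
]


def measure_nuclei(nuclei: np.ndarray, dapi_2d: np.ndarray | None = None,
                   pixel_size_um: float | None = None) -> pd.DataFrame:
    """Per-nucleus geometry: pixel-count area and Crofton (4-direction)
    perimeter, converted to physical units when the pixel size is known
    (otherwise the ``_um`` columns are NaN and pixel units apply).
    """
    nuclei = np.asarray(nuclei)
    props = ["label", "centroid", "area", "perimeter_crofton"]
    if dapi_2d is not None:
        props.append("intensity_mean")
    tbl = regionprops_table(nuclei, intensity_image=dapi_2d, properties=props)
    df = pd.DataFrame(tbl)
    if df.empty:
        return pd.DataFrame(columns=NUCLEUS_COLUMNS)
    df = df.rename(columns={
        "label": "nucleus_id",
        "centroid-0": "centroid_y",
        "centroid-1": "centroid_x",
        "area": "area_px2",
        "perimeter_crofton": "perimeter_px",
        "intensity_mean": "mean_dapi",
    })
    if "mean_dapi" not in df:
        df["mean_dapi"] = np.nan
    ps = pixel_size_um
    df["area_um2"] = df["area_px2"] * ps**2 if ps else np.nan
    df["perimeter_um"] = df["perimeter_px"] * ps if ps else np.nan
    df["cell_id"] = 0
    df["border_censored"] = _touches_border(nuclei, df["nucleus_id"].to_numpy())
    return df[NUCLEUS_COLUMNS]


def _touches_border(labels: np.ndarray, ids: np.ndarray) -> np.ndarray:
    edge = np.unique(np.concatenate([
        labels[0], labels[-1], labels[:, 0], labels[:, -1]
    ]))
    edge = set(edge[edge > 0].tolist())
    return np.array([int(i) in edge for i in ids])


@dataclass(frozen=True)
class VehicleReference:
    """Vehicle-arm nuclear-size statistics and the derived 3-sigma thresholds."""

    n_nuclei: int
    mean_area: float
    sd_area: float
    mean_perimeter: float
    sd_perimeter: float
    units: str = "um"  # or "px"

    @property
    def area_threshold(self) -> float:
        return self.mean_area + 3.0 * self.sd_area

    @property
    def perimeter_threshold(self) -> float:
        return self.mean_perimeter + 3.0 * self.sd_perimeter


def build_vehicle_reference(vehicle_nuclei: pd.DataFrame) -> VehicleReference:
    """Sample mean and SD (n-1 denominator) of uncensored vehicle nuclei.

    Raises ``ValueError`` with fewer than two usable nuclei; warns when the
    SD degenerates to zero (all nuclei identical).
    """
    df = vehicle_nuclei
    if "border_censored" in df:
        df = df[~df["border_censored"].astype(bool)]
    if len(df) < 2:
        raise ValueError("insufficient vehicle reference: need >= 2 nuclei")
    if df["area_um2"].notna().all():
        area, perim, units = df["area_um2"], df["perimeter_um"], "um"
    else:
        area, perim, units = df["area_px2"], df["perimeter_px"], "px"
    sd_area = float(area.std(ddof=1))
    sd_perim = float(perim.std(ddof=1))
    if sd_area == 0 or sd_perim == 0:
        warnings.warn("vehicle reference SD is zero; thresholds equal the mean")
    return VehicleReference(
        n_nuclei=len(df),
        mean_area=float(area.mean()),
        sd_area=sd_area,
        mean_perimeter=float(perim.mean()),
        sd_perimeter=sd_perim,
        units=units,
    )


def aggregate_cells(mapping: dict[int, list[int]],
                    nuclei_records: pd.DataFrame,
                    flagged_cells: set[int] | None = None) -> pd.DataFrame:
    """Per-cell totals by summing member-nucleus measurements exactly."""
    flagged_cells = flagged_cells or set()
    by_id = nuclei_records.set_index("nucleus_id")
    rows = []
    for cell_id, nucleus_ids in sorted(mapping.items()):
        missing = [n for n in nucleus_ids if n not in by_id.index]
        if missing:
            raise KeyError(f"nuclei without records: {missing}")
        sub = by_id.loc[nucleus_ids]
        rows.append(dict(
            cell_id=cell_id,
            n_nuclei=len(nucleus_ids),
            nucleus_ids=";".join(str(n) for n in nucleus_ids),
            total_area_px2=float(sub["area_px2"].sum()),
            total_area_um2=float(sub["area_um2"].sum()),
            total_perimeter_px=float(sub["perimeter_px"].sum()),
            total_perimeter_um=float(sub["perimeter_um"].sum()),
            is_mnc=len(nucleus_ids) > 1,
            flagged=cell_id in flagged_cells,
        ))
    return pd.DataFrame(rows, columns=CELL_COLUMNS)


@dataclass
class ClassificationSummary:
    group: str
    n_cells: int
    n_giant: int
    n_mnc: int | None
    n_giant_and_mnc: int | None
    pct_giant: float
    pct_mnc: float | None
    mean_total_area: float
    sem_total_area: float
    mean_total_perimeter: float
    sem_total_perimeter: float

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def classify_cells(cells: pd.DataFrame, ref: VehicleReference,
                   group: str = "", rule: str = "mean_plus_3sd",
                   mnc_available: bool = True):
    """Apply the giant/multinucleated classifier to per-cell totals.

    ``rule`` selects the giant criterion: ``mean_plus_3sd`` (default; total
    area or perimeter strictly above vehicle mean + 3 SD) or ``3sd_abs`` (the
    literal alternative, strictly above 3 SD regardless of the mean).  Either
    exceedance — area OR perimeter — suffices.

    Returns ``(cells_with_flags, ClassificationSummary)``.  With
    ``mnc_available=False`` (no cell-body channel), multinucleation cannot be
    determined and the MNC fields are reported as unavailable (``None``),
    not zero.
    """
    if rule == "mean_plus_3sd":
        area_thr = ref.area_threshold
        perim_thr = ref.perimeter_threshold
    elif rule == "3sd_abs":
        area_thr = 3.0 * ref.sd_area
        perim_thr = 3.0 * ref.sd_perimeter
    else:
        raise ValueError(f"unknown gc rule {rule!r}")

    out = cells.copy()
    if out.empty:
        out["is_giant"] = pd.Series(dtype=bool)
        summary = ClassificationSummary(
            group=group, n_cells=0, n_giant=0,
            n_mnc=0 if mnc_available else None,
            n_giant_and_mnc=0 if mnc_available else None,
            pct_giant=float("nan"),
            pct_mnc=float("nan") if mnc_available else None,
            mean_total_area=float("nan"), sem_total_area=float("nan"),
            mean_total_perimeter=float("nan"),
            sem_total_perimeter=float("nan"),
        )
        return out, summary

    if ref.units == "um":
        area = out["total_area_um2"]
        perim = out["total_perimeter_um"]
    else:
        area = out["total_area_px2"]
        perim = out["total_perimeter_px"]
    out["is_giant"] = (area > area_thr) | (perim > perim_thr)
    out["is_mnc"] = out["n_nuclei"] > 1

    n = len(out)
    n_giant = int(out["is_giant"].sum())
    if mnc_available:
        n_mnc = int(out["is_mnc"].sum())
        n_both = int((out["is_giant"] & out["is_mnc"]).sum())
        pct_mnc = 100.0 * n_mnc / n
    else:
        n_mnc = n_both = pct_mnc = None
    summary = ClassificationSummary(
        group=group,
        n_cells=n,
        n_giant=n_giant,
        n_mnc=n_mnc,
        n_giant_and_mnc=n_both,
        pct_giant=100.0 * n_giant / n,
        pct_mnc=pct_mnc,
        mean_total_area=float(area.mean()),
        sem_total_area=float(area.sem()),
        mean_total_perimeter=float(perim.mean()),
        sem_total_perimeter=float(perim.sem()),
    )
    return out, summary


def confluence(mask_or_labels: np.ndarray,
               pixel_size_um: float | None = None) -> dict:
    """Occupied image fraction and area — the live-cell proliferation read-out
    (total cell-covered area per field)."""
    arr = np.asarray(mask_or_labels)
    occupied_px = int(np.count_nonzero(arr))
    total_px = arr.size
    result = dict(
        occupied_px=occupied_px,
        total_px=total_px,
        fraction=occupied_px / total_px if total_px else 0.0,
    )
    if pixel_size_um:
        result["occupied_um2"] = occupied_px * pixel_size_um**2
    return result
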