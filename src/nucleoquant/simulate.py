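"""Ground-truthed synthetic fluorescence-microscopy scenes.

Emulates DAPI-stained ovarian/fallopian-tube cultures chronically exposed to
arsenite versus vehicle: a vehicle arm with unimodally distributed nuclear
sizes, and an exposed arm enriched for giant cells (enlarged nuclei) and
multinucleated cells (several nuclei sharing one cell body).  Every scene is
rendered together with exact ground truth (per-nucleus ellipse geometry,
per-cell giant/multinucleated flags, planted nuclear:cytosolic marker ratio,
planted focus counts), so each downstream measurement can be validated against
a known answer.

Channels rendered per scene:

``DAPI``
    each nucleus as a filled ellipse on a flat background.
``MARKER``
    a translocation/damage marker: cytosol at a fixed level, nuclear interior
    at ``marker_ratio`` times that level, plus optional Gaussian foci.
``CELLBODY``
    a convex (disk) cell-body region containing all of a cell's nuclei.

Noise is applied last: Poisson shot noise on the rendered counts, then
additive Gaussian read noise, independently per z-plane.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SceneConfig",
    "NucleusTruth",
    "CellTruth",
    "SceneGroundTruth",
    "generate_scene",
    "generate_population",
    "ellipse_mask",
    "ellipse_perimeter",
]


# --------------------------------------------------------------------------- #
# configuration
# --------------------------------------------------------------------------- #


@dataclass(frozen=True)
class SceneConfig:
    """Parameters of one synthetic scene.

    Defaults describe the vehicle arm of the study conditions: a 768x768 px
    field at 0.5 um/px with 40 well-separated mononucleated cells whose
    nuclear areas follow a log-normal distribution (mean 100 um^2, CV 0.1).
    The exposed arm is obtained by raising ``giant_fraction`` /
    ``mnc_fraction``.

    Notes on the flag draws: giant and multinucleated status are drawn with
    maximal overlap (multinucleated cells are a subset of giant cells whenever
    ``mnc_fraction <= giant_fraction``) while preserving both marginal
    fractions exactly.  A cell that is multinucleated without being giant
    would unavoidably be classified giant by the summed-area/perimeter rule,
    which is why the populations are nested, mirroring cultures where
    multinucleated cells arise within the giant-cell compartment.
    """

    image_height_px: int = 768
    image_width_px: int = 768
    pixel_size_um: float = 0.5
    n_cells: int = 40
    vehicle_area_mean_um2: float = 100.0
    vehicle_area_cv: float = 0.1
    giant_fraction: float = 0.0
    giant_scale: float = 2.0  # multiplier on linear nuclear radius
    mnc_fraction: float = 0.0
    mnc_nuclei_range: tuple[int, int] = (2, 4)
    marker_ratio: float = 1.0  # planted nuclear:cytosolic mean-intensity ratio
    foci_lambda: float = 0.0  # Poisson mean foci per nucleus
    foci_sigma_px: float = 1.5
    background_level: float = 5.0
    gaussian_noise_sd: float = 2.0
    poisson_noise: bool = True
    seed: int = 0
    # rendering levels (counts); foci peak amplitude is
    # foci_amplitude_factor * cytosol_level, kept >= 5x by validation
    n_z: int = 1
    dapi_level: float = 120.0
    cytosol_level: float = 20.0
    cellbody_level: float = 40.0
    foci_amplitude_factor: float = 6.0

    def __post_init__(self) -> None:
        if self.image_height_px <= 0 or self.image_width_px <= 0:
            raise ValueError("image dimensions must be positive")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        if self.n_cells < 0:
            raise ValueError("n_cells must be non-negative")
        if self.vehicle_area_mean_um2 <= 0:
            raise ValueError("vehicle_area_mean_um2 must be positive")
        if not 0.0 < self.vehicle_area_cv < 1.0:
            raise ValueError("vehicle_area_cv must lie in (0, 1)")
        for name in ("giant_fraction", "mnc_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.giant_scale <= 1.0:
            raise ValueError("giant_scale must exceed 1")
        lo, hi = self.mnc_nuclei_range
        if lo < 2 or hi < lo:
            raise ValueError("mnc_nuclei_range must satisfy 2 <= min <= max")
        if self.marker_ratio <= 0:
            raise ValueError("marker_ratio must be positive")
        if self.foci_lambda < 0:
            raise ValueError("foci_lambda must be non-negative")
        if self.foci_sigma_px <= 0:
            raise ValueError("foci_sigma_px must be positive")
        if self.background_level < 0 or self.gaussian_noise_sd < 0:
            raise ValueError("noise/background levels must be non-negative")
        if self.n_z < 1:
            raise ValueError("n_z must be >= 1")
        if self.foci_amplitude_factor < 5.0:
            raise ValueError(
                "foci_amplitude_factor must be >= 5 so planted foci stay "
                "unambiguously above the cytosolic marker mean"
            )

    def replace(self, **kwargs) -> "SceneConfig":
        return dataclasses.replace(self, **kwargs)

    @classmethod
    def from_dict(cls, d: dict) -> "SceneConfig":
        d = dict(d)
        if "mnc_nuclei_range" in d:
            d["mnc_nuclei_range"] = tuple(d["mnc_nuclei_range"])
        return cls(**d)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["mnc_nuclei_range"] = list(self.mnc_nuclei_range)
        return d


# --------------------------------------------------------------------------- #
# ground truth
# --------------------------------------------------------------------------- #


@dataclass
class NucleusTruth:
    nucleus_id: int
    cell_id: int
    center_yx: tuple[float, float]  # px, (row, col)
    semi_major_px: float
    semi_minor_px: float
    theta_rad: float
    area_um2: float
    perimeter_um: float
    foci_count: int
    foci_yx: list[tuple[float, float]] = field(default_factory=list)


@dataclass
class CellTruth:
    cell_id: int
    nucleus_ids: list[int]
    center_yx: tuple[float, float]
    body_radius_px: float
    is_giant_true: bool
    is_mnc_true: bool
    planted_ratio: float
    total_area_um2: float
    total_perimeter_um: float


@dataclass
class SceneGroundTruth:
    """Generator-side truth for one scene; the oracle for every read-out."""

    config: SceneConfig
    seed: int
    cells: list[CellTruth]
    nuclei: list[NucleusTruth]

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    def nuclei_frame(self) -> pd.DataFrame:
        rows = [
            dict(
                nucleus_id=n.nucleus_id,
                cell_id=n.cell_id,
                center_y=n.center_yx[0],
                center_x=n.center_yx[1],
                semi_major_px=n.semi_major_px,
                semi_minor_px=n.semi_minor_px,
                theta_rad=n.theta_rad,
                area_um2=n.area_um2,
                perimeter_um=n.perimeter_um,
                foci_count=n.foci_count,
            )
            for n in self.nuclei
        ]
        return pd.DataFrame(
            rows,
            columns=[
                "nucleus_id", "cell_id", "center_y", "center_x",
                "semi_major_px", "semi_minor_px", "theta_rad",
                "area_um2", "perimeter_um", "foci_count",
            ],
        )

    def cells_frame(self) -> pd.DataFrame:
        rows = [
            dict(
                cell_id=c.cell_id,
                n_nuclei=len(c.nucleus_ids),
                is_giant_true=c.is_giant_true,
                is_mnc_true=c.is_mnc_true,
                planted_ratio=c.planted_ratio,
                total_area_um2=c.total_area_um2,
                total_perimeter_um=c.total_perimeter_um,
            )
            for c in self.cells
        ]
        return pd.DataFrame(
            rows,
            columns=[
                "cell_id", "n_nuclei", "is_giant_true", "is_mnc_true",
                "planted_ratio", "total_area_um2", "total_perimeter_um",
            ],
        )

    def nucleus_label_map(self) -> np.ndarray:
        """Rasterize the true nuclei with the generator's own pixel rule."""
        shape = (self.config.image_height_px, self.config.image_width_px)
        labels = np.zeros(shape, dtype=np.int32)
        for n in self.nuclei:
            sl, m = ellipse_mask(
                shape, n.center_yx, n.semi_major_px, n.semi_minor_px, n.theta_rad
            )
            labels[sl][m] = n.nucleus_id
        return labels

    def cell_label_map(self) -> np.ndarray:
        shape = (self.config.image_height_px, self.config.image_width_px)
        labels = np.zeros(shape, dtype=np.int32)
        for c in self.cells:
            sl, m = disk_mask(shape, c.center_yx, c.body_radius_px)
            labels[sl][m] = c.cell_id
        return labels

    def to_json(self) -> str:
        payload = dict(
            seed=self.seed,
            config=self.config.to_dict(),
            cells=[dataclasses.asdict(c) for c in self.cells],
            nuclei=[dataclasses.asdict(n) for n in self.nuclei],
        )
        return json.dumps(payload, indent=1)


# --------------------------------------------------------------------------- #
# geometry helpers
# --------------------------------------------------------------------------- #


def ellipse_perimeter(a: float, b: float) -> float:
    """Ramanujan's second approximation to the ellipse perimeter."""
    h = ((a - b) / (a + b)) ** 2
    return math.pi * (a + b) * (1.0 + 3.0 * h / (10.0 + math.sqrt(4.0 - 3.0 * h)))


def _bbox_slices(shape, cy, cx, radius):
    y0 = max(int(math.floor(cy - radius - 1)), 0)
    y1 = min(int(math.ceil(cy + radius + 2)), shape[0])
    x0 = max(int(math.floor(cx - radius - 1)), 0)
    x1 = min(int(math.ceil(cx + radius + 2)), shape[1])
    return (slice(y0, y1), slice(x0, x1))


def ellipse_mask(shape, center_yx, a, b, theta):
    """Boolean mask of pixels whose centers fall inside the ellipse.

    Returns ``(slices, mask)`` restricted to the ellipse's bounding box so
    callers can index the full image with ``img[slices][mask]``.
    """
    cy, cx = center_yx
    sl = _bbox_slices(shape, cy, cx, max(a, b))
    yy, xx = np.mgrid[sl[0], sl[1]]
    dy = yy - cy
    dx = xx - cx
    ct, st = math.cos(theta), math.sin(theta)
    u = dx * ct + dy * st
    v = -dx * st + dy * ct
    mask = (u / a) ** 2 + (v / b) ** 2 <= 1.0
    return sl, mask


def disk_mask(shape, center_yx, radius):
    cy, cx = center_yx
    sl = _bbox_slices(shape, cy, cx, radius)
    yy, xx = np.mgrid[sl[0], sl[1]]
    mask = (yy - cy) ** 2 + (xx - cx) ** 2 <= radius**2
    return sl, mask


def _lognormal_areas(rng, n, mean, cv):
    sigma2 = math.log(1.0 + cv * cv)
    mu = math.log(mean) - sigma2 / 2.0
    return rng.lognormal(mean=mu, sigma=math.sqrt(sigma2), size=n)


# --------------------------------------------------------------------------- #
# scene generation
# --------------------------------------------------------------------------- #


class ScenePlacementError(RuntimeError):
    """Raised when nuclei/cells cannot be placed without overlap."""


def _draw_flags(rng, n, giant_fraction, mnc_fraction):
    # Maximal-overlap coupling: marginals are exact; MNC subset of giant when
    # mnc_fraction <= giant_fraction (see SceneConfig docstring).
    giant = rng.random(n) < giant_fraction
    if giant_fraction > 0:
        p_in = min(1.0, mnc_fraction / giant_fraction)
    else:
        p_in = 0.0
    if giant_fraction < 1.0:
        p_out = max(0.0, (mnc_fraction - giant_fraction * p_in) / (1.0 - giant_fraction))
    else:
        p_out = 0.0
    v = rng.random(n)
    mnc = np.where(giant, v < p_in, v < p_out)
    return giant, mnc


def _sample_nucleus_shape(rng, area_px2):
    """Semi-axes and rotation for a nucleus of the given pixel area."""
    q = rng.uniform(0.85, 1.0)  # near-round, like interphase DAPI nuclei
    ab = area_px2 / math.pi
    b = math.sqrt(ab * q)
    a = math.sqrt(ab / q)
    theta = rng.uniform(0.0, math.pi)
    return a, b, theta


def _place_nuclei_in_cell(rng, majors, gap=4.0, max_attempts=4000):
    """Non-overlapping offsets (local coords) for one cell's nuclei."""
    offsets = [(0.0, 0.0)]
    for i in range(1, len(majors)):
        r_try = 2.2 * max(majors)
        placed = False
        for attempt in range(max_attempts):
            ang = rng.uniform(0, 2 * math.pi)
            rad = r_try * math.sqrt(rng.random())
            oy, ox = rad * math.sin(ang), rad * math.cos(ang)
            ok = all(
                math.hypot(oy - py, ox - px) >= majors[i] + majors[j] + gap
                for j, (py, px) in enumerate(offsets)
            )
            if ok:
                offsets.append((oy, ox))
                placed = True
                break
            if attempt % 400 == 399:
                r_try *= 1.25
        if not placed:
            raise ScenePlacementError("could not place nuclei inside cell body")
    # recentre on the centroid so the cell body stays compact
    cy = sum(o[0] for o in offsets) / len(offsets)
    cx = sum(o[1] for o in offsets) / len(offsets)
    return [(oy - cy, ox - cx) for (oy, ox) in offsets]


def _place_foci(rng, k, a, b, theta, margin, min_sep, n_candidates=40):
    """Best-candidate (Mitchell) sampling of focus centers inside an ellipse.

    Keeps centers at least ``margin`` px from the boundary and favours
    pairwise separation >= ``min_sep`` px (best effort for large k).
    """
    aa = max(a - margin, 0.5)
    bb = max(b - margin, 0.5)
    ct, st = math.cos(theta), math.sin(theta)
    pts: list[tuple[float, float]] = []
    for _ in range(k):
        best = None
        best_d = -1.0
        for _ in range(n_candidates):
            # uniform in the unit disk, scaled into the shrunken ellipse
            ang = rng.uniform(0, 2 * math.pi)
            r = math.sqrt(rng.random())
            u = aa * r * math.cos(ang)
            v = bb * r * math.sin(ang)
            oy = u * st + v * ct
            ox = u * ct - v * st
            d = min(
                (math.hypot(oy - py, ox - px) for (py, px) in pts),
                default=float("inf"),
            )
            best_d_candidate = min(d, min_sep)  # beyond min_sep all equal
            if best_d_candidate > best_d:
                best_d = best_d_candidate
                best = (oy, ox)
        pts.append(best)
    return pts


def generate_scene(config: SceneConfig):
    """Render one scene and its exact ground truth.

    Returns ``(stack, truth)`` where ``stack`` is an
    :class:`~nucleoquant.imgio.ImageStack` with channels DAPI, MARKER,
    CELLBODY and ``truth`` is a :class:`SceneGroundTruth`.

    Raises :class:`ScenePlacementError` when the configuration is too dense
    for non-overlapping placement.
    """
    from .imgio import ImageStack  # local import to avoid a cycle

    rng = np.random.default_rng(config.seed)
    ps = config.pixel_size_um
    shape = (config.image_height_px, config.image_width_px)
    n = config.n_cells

    giant_flags, mnc_flags = _draw_flags(
        rng, n, config.giant_fraction, config.mnc_fraction
    )
    total_areas_um2 = _lognormal_areas(
        rng, n, config.vehicle_area_mean_um2, config.vehicle_area_cv
    )
    total_areas_um2 = np.where(
        giant_flags, total_areas_um2 * config.giant_scale**2, total_areas_um2
    )

    cells: list[CellTruth] = []
    nuclei: list[NucleusTruth] = []
    placed: list[tuple[float, float, float]] = []  # (cy, cx, r_cell)
    nucleus_id = 0

    for i in range(n):
        if mnc_flags[i]:
            lo, hi = config.mnc_nuclei_range
            k = int(rng.integers(lo, hi + 1))
        else:
            k = 1
        # split the cell's nuclear content among its nuclei with mild jitter
        if k > 1:
            w = rng.dirichlet(np.full(k, 20.0))
        else:
            w = np.ones(1)
        areas_px2 = total_areas_um2[i] * w / ps**2
        shapes = [_sample_nucleus_shape(rng, a) for a in areas_px2]
        majors = [s[0] for s in shapes]
        offsets = _place_nuclei_in_cell(rng, majors) if k > 1 else [(0.0, 0.0)]
        r_need = max(
            math.hypot(oy, ox) + s[0] for (oy, ox), s in zip(offsets, shapes)
        )
        r_cell = r_need + 6.0

        # place the cell body without overlapping previously placed bodies
        placed_ok = False
        for attempt in range(3000):
            cy = rng.uniform(r_cell + 2.0, shape[0] - r_cell - 2.0)
            cx = rng.uniform(r_cell + 2.0, shape[1] - r_cell - 2.0)
            if all(
                math.hypot(cy - py, cx - px) >= r_cell + pr + 3.0
                for (py, px, pr) in placed
            ):
                placed_ok = True
                break
        if not placed_ok:
            raise ScenePlacementError(
                f"could not place cell {i + 1}/{n}: configuration too dense"
            )
        placed.append((cy, cx, r_cell))

        cell_id = i + 1
        nid_list = []
        tot_area = 0.0
        tot_perim = 0.0
        for (oy, ox), (a, b, theta), area_px2 in zip(offsets, shapes, areas_px2):
            nucleus_id += 1
            nid_list.append(nucleus_id)
            kf = int(rng.poisson(config.foci_lambda))
            # keep foci clear of the nuclear rim: past the detector's
            # boundary-exclusion band plus the spot's own extent
            margin = max(2.0 * config.foci_sigma_px, 3.0) + 3.0
            min_sep = max(6.0, 4.0 * config.foci_sigma_px)
            foci_local = _place_foci(rng, kf, a, b, theta, margin, min_sep)
            area_um2 = area_px2 * ps**2
            perim_um = ellipse_perimeter(a, b) * ps
            nuclei.append(
                NucleusTruth(
                    nucleus_id=nucleus_id,
                    cell_id=cell_id,
                    center_yx=(cy + oy, cx + ox),
                    semi_major_px=a,
                    semi_minor_px=b,
                    theta_rad=theta,
                    area_um2=area_um2,
                    perimeter_um=perim_um,
                    foci_count=kf,
                    foci_yx=[(cy + oy + fy, cx + ox + fx) for fy, fx in foci_local],
                )
            )
            tot_area += area_um2
            tot_perim += perim_um
        cells.append(
            CellTruth(
                cell_id=cell_id,
                nucleus_ids=nid_list,
                center_yx=(cy, cx),
                body_radius_px=r_cell,
                is_giant_true=bool(giant_flags[i]),
                is_mnc_true=bool(mnc_flags[i]),
                planted_ratio=config.marker_ratio,
                total_area_um2=tot_area,
                total_perimeter_um=tot_perim,
            )
        )

    truth = SceneGroundTruth(config=config, seed=config.seed, cells=cells, nuclei=nuclei)
    base = _render(truth, config)
    planes = _apply_noise(base, config, rng)
    stack = ImageStack(
        pixels=planes,
        channel_names=("DAPI", "MARKER", "CELLBODY"),
        pixel_size_um=ps,
    )
    return stack, truth


def _render(truth: SceneGroundTruth, config: SceneConfig) -> np.ndarray:
    """Noise-free rendering, shape (3, y, x): DAPI, MARKER, CELLBODY."""
    shape = (config.image_height_px, config.image_width_px)
    bg = config.background_level
    dapi = np.full(shape, bg, dtype=float)
    marker = np.full(shape, bg, dtype=float)
    body = np.full(shape, bg, dtype=float)

    for c in truth.cells:
        sl, m = disk_mask(shape, c.center_yx, c.body_radius_px)
        body[sl][m] = bg + config.cellbody_level
        # marker levels are set (not added) so the planted ratio is exact
        marker[sl][m] = config.cytosol_level
    for nuc in truth.nuclei:
        sl, m = ellipse_mask(
            shape, nuc.center_yx, nuc.semi_major_px, nuc.semi_minor_px, nuc.theta_rad
        )
        dapi[sl][m] = bg + config.dapi_level
        marker[sl][m] = config.marker_ratio * config.cytosol_level
    # foci: additive isotropic Gaussian spots on the marker channel
    amp = config.foci_amplitude_factor * config.cytosol_level
    sig = config.foci_sigma_px
    for nuc in truth.nuclei:
        for fy, fx in nuc.foci_yx:
            sl = _bbox_slices(shape, fy, fx, 4 * sig)
            yy, xx = np.mgrid[sl[0], sl[1]]
            marker[sl] += amp * np.exp(
                -((yy - fy) ** 2 + (xx - fx) ** 2) / (2.0 * sig**2)
            )
    return np.stack([dapi, marker, body])


def _apply_noise(base: np.ndarray, config: SceneConfig, rng) -> np.ndarray:
    """Poisson shot noise then additive Gaussian, per z-plane; returns (c,z,y,x)."""
    planes = np.empty((base.shape[0], config.n_z) + base.shape[1:], dtype=float)
    for z in range(config.n_z):
        img = base
        if config.poisson_noise:
            img = rng.poisson(img).astype(float)
        if config.gaussian_noise_sd > 0:
            img = img + rng.normal(0.0, config.gaussian_noise_sd, size=img.shape)
        planes[:, z] = np.clip(img, 0.0, None)
    return planes


def generate_population(
    vehicle_config: SceneConfig,
    exposed_config: SceneConfig,
    n_scenes: int,
    master_seed: int | None = None,
):
    """Paired vehicle / exposed scene lists with derived per-scene seeds.

    The vehicle arm must have ``giant_fraction == mnc_fraction == 0`` (it is
    the classifier's reference population).  Per-scene seeds are derived from
    ``master_seed`` through a :class:`numpy.random.SeedSequence`, so scene k
    is reproducible independently of generation order.
    """
    if n_scenes < 1:
        raise ValueError("n_scenes must be positive")
    if vehicle_config.giant_fraction != 0 or vehicle_config.mnc_fraction != 0:
        raise ValueError("vehicle arm must have giant_fraction = mnc_fraction = 0")
    if master_seed is None:
        master_seed = vehicle_config.seed
    seeds = np.random.SeedSequence(master_seed).generate_state(2 * n_scenes) % (2**31)
    vehicle = [
        generate_scene(vehicle_config.replace(seed=int(seeds[i])))
        for i in range(n_scenes)
    ]
    exposed = [
        generate_scene(exposed_config.replace(seed=int(seeds[n_scenes + i])))
        for i in range(n_scenes)
    ]
    return vehicle, exposed
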