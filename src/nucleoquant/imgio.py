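"""Image-stack container and TIFF / tabular I/O.

The in-memory container is a thin ``(channel, z, y, x)`` array wrapper with
channel names and a physical pixel size.  Stacks are written as multi-page
TIFF, one page per (channel, z) plane, with a JSON description on the first
page recording channel names, z-depth and pixel size so a written stack
round-trips exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

CANONICAL_CHANNELS = ("DAPI", "MARKER", "CELLBODY")


@dataclass
class ImageStack:
    """Multi-channel pixel data indexed (channel, z, y, x)."""

    pixels: np.ndarray
    channel_names: tuple[str, ...]
    pixel_size_um: float | None = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim == 2:
            self.pixels = self.pixels[None, None]
        elif self.pixels.ndim == 3:
            self.pixels = self.pixels[:, None]
        if self.pixels.ndim != 4:
            raise ValueError("pixels must be (channel, z, y, x)")
        self.channel_names = tuple(self.channel_names)
        if len(self.channel_names) != self.pixels.shape[0]:
            raise ValueError("one channel name per channel required")
        if len(set(self.channel_names)) != len(self.channel_names):
            raise ValueError("channel names must be unique")
        if np.any(self.pixels < 0):
            raise ValueError("intensities must be non-negative")
        if self.pixel_size_um is not None and self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive when given")

    @property
    def n_channels(self) -> int:
        return self.pixels.shape[0]

    @property
    def n_z(self) -> int:
        return self.pixels.shape[1]

    @property
    def shape_yx(self) -> tuple[int, int]:
        return self.pixels.shape[2], self.pixels.shape[3]

    def channel(self, name: str, z: int | None = None) -> np.ndarray:
        """A single channel; 2D when the stack has one plane or ``z`` given."""
        try:
            ci = self.channel_names.index(name)
        except ValueError:
            raise KeyError(f"channel {name!r} not in stack {self.channel_names}")
        data = self.pixels[ci]
        if z is not None:
            return data[z]
        return data[0] if data.shape[0] == 1 else data

    def has_channel(self, name: str) -> bool:
        return name in self.channel_names


def write_stack(stack: ImageStack, path) -> None:
    """Write one page per (channel, z) plane with a JSON header description."""
    path = Path(path)
    meta = {
        "nucleoquant": 1,
        "channel_names": list(stack.channel_names),
        "n_z": stack.n_z,
        "pixel_size_um": stack.pixel_size_um,
    }
    pages = stack.pixels.reshape((-1,) + stack.pixels.shape[2:]).astype(np.float32)
    tifffile.imwrite(path, pages, photometric="minisblack",
                     description=json.dumps(meta))


def read_stack(path, channel_map: dict | None = None,
               pixel_size_um: float | None = None) -> ImageStack:
    """Read a TIFF/OME-TIFF into an :class:`ImageStack`.

    Stacks written by :func:`write_stack` carry their own metadata and need no
    ``channel_map``.  For foreign TIFFs, ``channel_map`` assigns roles to page
    indices, e.g. ``{"DAPI": 0, "MARKER": 1}``; a DAPI role is mandatory.
    ``pixel_size_um`` overrides or supplies the physical scale.
    """
    path = Path(path)
    with tifffile.TiffFile(path) as tf:
        page_arrays = [p.asarray() for p in tf.pages]
        desc = tf.pages[0].description or ""
    if len({a.shape for a in page_arrays}) != 1 or page_arrays[0].ndim != 2:
        raise ValueError("inconsistent dimensions: TIFF pages differ in shape")
    pages = np.asarray(page_arrays)

    meta = None
    if desc:
        try:
            cand = json.loads(desc)
            if isinstance(cand, dict) and cand.get("nucleoquant"):
                meta = cand
        except (json.JSONDecodeError, UnicodeDecodeError):
            meta = None

    if meta is not None:
        names = tuple(meta["channel_names"])
        n_z = int(meta["n_z"])
        ps = pixel_size_um if pixel_size_um is not None else meta.get("pixel_size_um")
        pixels = pages.reshape(len(names), n_z, *pages.shape[1:])
        return ImageStack(pixels=pixels, channel_names=names, pixel_size_um=ps)

    if not channel_map:
        raise ValueError("channel_map required for TIFFs without embedded metadata")
    if "DAPI" not in channel_map:
        raise ValueError("channel_map must assign a DAPI role")
    names = tuple(channel_map)
    pixels = np.stack([pages[channel_map[name]] for name in names])
    return ImageStack(pixels=pixels, channel_names=names, pixel_size_um=pixel_size_um)


def max_project(stack: ImageStack) -> ImageStack:
    """Maximum-intensity projection over z; idempotent."""
    return ImageStack(
        pixels=stack.pixels.max(axis=1, keepdims=True),
        channel_names=stack.channel_names,
        pixel_size_um=stack.pixel_size_um,
    )


def sum_project(stack: ImageStack) -> ImageStack:
    return ImageStack(
        pixels=stack.pixels.sum(axis=1, keepdims=True),
        channel_names=stack.channel_names,
        pixel_size_um=stack.pixel_size_um,
    )


def select_plane(stack: ImageStack, k: int) -> ImageStack:
    return ImageStack(
        pixels=stack.pixels[:, k : k + 1],
        channel_names=stack.channel_names,
        pixel_size_um=stack.pixel_size_um,
    )


def reduce_z(stack: ImageStack, mode: str = "max") -> ImageStack:
    """Reduce a z-stack to a single plane: ``max``, ``sum`` or ``plane:<k>``."""
    if mode == "max":
        return max_project(stack)
    if mode == "sum":
        return sum_project(stack)
    if mode.startswith("plane:"):
        return select_plane(stack, int(mode.split(":", 1)[1]))
    raise ValueError(f"unknown z mode {mode!r}")


def write_labels(labels: np.ndarray, path) -> None:
    labels = np.asarray(labels)
    if labels.max(initial=0) > np.iinfo(np.uint16).max:
        raise ValueError("too many labels for 16-bit storage")
    tifffile.imwrite(Path(path), labels.astype(np.uint16))


def read_labels(path) -> np.ndarray:
    return tifffile.imread(Path(path)).astype(np.int32)


def write_results(nuclei: pd.DataFrame, cells: pd.DataFrame, summary: dict,
                  out_dir) -> dict[str, Path]:
    """Write per-nucleus CSV, per-cell CSV and a per-scene summary JSON.

    Returns the written paths.  Numeric columns survive a CSV round-trip at
    full double precision (pandas writes ``repr``-faithful floats).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "nuclei": out / "nuclei.csv",
        "cells": out / "cells.csv",
        "summary": out / "summary.json",
    }
    # %.17g keeps doubles round-trip exact through the CSV
    nuclei.to_csv(paths["nuclei"], index=False, float_format="%.17g")
    cells.to_csv(paths["cells"], index=False, float_format="%.17g")
    with open(paths["summary"], "w") as fh:
        json.dump(summary, fh, indent=1, default=_json_default)
    return paths


def read_table(path) -> pd.DataFrame:
    """Read a results CSV with a correctly-rounded float parser, so numeric
    fields round-trip :func:`write_results` at full double precision."""
    return pd.read_csv(path, float_precision="round_trip")


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
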