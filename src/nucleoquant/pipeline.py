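"""End-to-end orchestration: simulate -> segment -> measure -> classify ->
quantify intensities -> summarize, plus the parameter-recovery benchmark that
re-measures planted ground truth through the whole pipeline.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from . import __version__
from .imgio import ImageStack, reduce_z, write_labels, write_results
from .intensity import FociParams, cytosolic_intensity, detect_foci, nuclear_cytosolic_ratio
from .morphometry import (
    ClassificationSummary,
    aggregate_cells,
    build_vehicle_reference,
    classify_cells,
    measure_nuclei,
)
from .segment import SegmentationParams, assign_nuclei_to_cells, segment_cells, segment_nuclei
from .simulate import SceneConfig, generate_population, generate_scene
from .synthtables import generate_ct_table, generate_gene_stats
from .quantstats import bh_adjust, ddct_fold_changes, deg_filter, molar_to_mass_conc


@dataclass
class QuantifyResult:
    """Per-scene quantification bundle."""

    nuclei: pd.DataFrame
    cells: pd.DataFrame
    nucleus_labels: np.ndarray
    cell_labels: np.ndarray
    mapping: dict[int, list[int]]
    mnc_available: bool
    fallback_cells: list[int] = field(default_factory=list)


def quantify_scene(stack: ImageStack,
                   seg_params: SegmentationParams | None = None,
                   foci_params: FociParams | None = None,
                   z_mode: str = "max",
                   cytosol_mode: str = "whole_cell",
                   count_foci: bool = False) -> QuantifyResult:
    """Run segmentation and all measurements on one stack.

    Requires a DAPI channel.  With a CELLBODY channel, nuclei are grouped
    into cells (multinucleation is callable); without one, each nucleus is
    its own cell and MNC status is reported unavailable.  With a MARKER
    channel, per-cell nuclear/cytosolic intensities and ratios are measured;
    ``count_foci=True`` additionally counts marker foci per nucleus/cell.
    """
    if seg_params is None:
        seg_params = SegmentationParams()
    if not stack.has_channel("DAPI"):
        raise ValueError("quantify: stack has no DAPI channel")
    flat = reduce_z(stack, z_mode)
    dapi = flat.channel("DAPI")

    nucleus_labels = segment_nuclei(dapi, seg_params)

    mnc_available = stack.has_channel("CELLBODY")
    fallback: list[int] = []
    if mnc_available:
        body = flat.channel("CELLBODY")
        cell_labels, fallback = segment_cells(body, nucleus_labels, seg_params)
        mapping = assign_nuclei_to_cells(nucleus_labels, cell_labels)
        mapping.pop(0, None)
    else:
        cell_labels = nucleus_labels.copy()
        mapping = {int(n): [int(n)] for n in np.unique(nucleus_labels) if n > 0}

    nuclei_df = measure_nuclei(nucleus_labels, dapi, stack.pixel_size_um)
    nucleus_to_cell = {n: c for c, ns in mapping.items() for n in ns}
    if not nuclei_df.empty:
        nuclei_df["cell_id"] = nuclei_df["nucleus_id"].map(nucleus_to_cell).fillna(0).astype(int)
    cells_df = aggregate_cells(mapping, nuclei_df, set(fallback)) if mapping else \
        aggregate_cells({}, nuclei_df)

    if stack.has_channel("MARKER") and not cells_df.empty:
        marker = flat.channel("MARKER")
        _measure_marker(marker, cell_labels, nucleus_labels, mapping, cells_df,
                        cytosol_mode)
        if count_foci:
            per_nuc, per_cell = detect_foci(marker, nucleus_labels, foci_params,
                                            mapping=mapping)
            nuclei_df["foci_count"] = nuclei_df["nucleus_id"].map(per_nuc).fillna(0).astype(int)
            cells_df["foci_count"] = cells_df["cell_id"].map(per_cell).fillna(0).astype(int)

    return QuantifyResult(
        nuclei=nuclei_df, cells=cells_df,
        nucleus_labels=nucleus_labels, cell_labels=cell_labels,
        mapping=mapping, mnc_available=mnc_available,
        fallback_cells=fallback,
    )


def _measure_marker(marker, cell_labels, nucleus_labels, mapping, cells_df,
                    cytosol_mode):
    """Attach per-cell marker columns in place (bounding-box restricted)."""
    slices = ndi.find_objects(cell_labels)
    cyto_col, nmean_col, ratio_col = [], [], []
    for cid in cells_df["cell_id"]:
        sl = slices[cid - 1]
        cmask = cell_labels[sl] == cid
        nmask = np.isin(nucleus_labels[sl], mapping[cid]) & cmask
        sub = marker[sl]
        nuclear_mean = float(sub[nmask].mean()) if nmask.any() else float("nan")
        try:
            cyto = cytosolic_intensity(sub, cmask, nmask, mode=cytosol_mode)
            ratio = nuclear_mean / cyto if cyto > 0 else float("nan")
        except ValueError:
            cyto, ratio = float("nan"), float("nan")
        cyto_col.append(cyto)
        nmean_col.append(nuclear_mean)
        ratio_col.append(ratio)
    cells_df["cyto_intensity"] = cyto_col
    cells_df["nuclear_mean"] = nmean_col
    cells_df["ratio"] = ratio_col
    cells_df["ratio_defined"] = np.isfinite(ratio_col)


def quantify_arm(scenes, **kwargs):
    """Quantify a list of ``(stack, truth)`` pairs (or bare stacks) and pool
    per-nucleus / per-cell tables with a ``scene_id`` column and globally
    unique ids."""
    nuclei_frames, cell_frames, results = [], [], []
    cell_offset = 0
    nuc_offset = 0
    for k, scene in enumerate(scenes):
        stack = scene[0] if isinstance(scene, tuple) else scene
        res = quantify_scene(stack, **kwargs)
        n = res.nuclei.copy()
        c = res.cells.copy()
        n["scene_id"] = k
        c["scene_id"] = k
        n["nucleus_id"] += nuc_offset
        n["cell_id"] += cell_offset
        c["cell_id"] += cell_offset
        nuc_offset += len(n)
        cell_offset += len(c)
        nuclei_frames.append(n)
        cell_frames.append(c)
        results.append(res)
    nuclei = pd.concat(nuclei_frames, ignore_index=True) if nuclei_frames else pd.DataFrame()
    cells = pd.concat(cell_frames, ignore_index=True) if cell_frames else pd.DataFrame()
    return nuclei, cells, results


def run_quantify(stack: ImageStack, out_dir,
                 seg_params: SegmentationParams | None = None,
                 foci_params: FociParams | None = None,
                 z_mode: str = "max", cytosol_mode: str = "whole_cell",
                 count_foci: bool = False, seed: int | None = None):
    """Quantify one stack and write CSVs, label TIFFs and a run manifest."""
    from pathlib import Path

    res = quantify_scene(stack, seg_params=seg_params, foci_params=foci_params,
                         z_mode=z_mode, cytosol_mode=cytosol_mode,
                         count_foci=count_foci)
    summary = {
        "n_nuclei": int(len(res.nuclei)),
        "n_cells": int(len(res.cells)),
        "mnc_available": res.mnc_available,
    }
    paths = write_results(res.nuclei, res.cells, summary, out_dir)
    out = Path(out_dir)
    write_labels(res.nucleus_labels, out / "nucleus_labels.tif")
    write_labels(res.cell_labels, out / "cell_labels.tif")
    manifest = {
        "version": __version__,
        "seed": seed,
        "z_mode": z_mode,
        "cytosol_mode": cytosol_mode,
        "seg_params": (seg_params or SegmentationParams()).__dict__,
        "config_hash": _config_hash(seg_params, foci_params, z_mode, cytosol_mode),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return res, paths


def _config_hash(*parts) -> str:
    blob = json.dumps([getattr(p, "__dict__", p) for p in parts],
                      sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


# --------------------------------------------------------------------------- #
# classification over arms
# --------------------------------------------------------------------------- #


def classify_arms(vehicle_scenes, exposed_scenes,
                  seg_params: SegmentationParams | None = None):
    """Quantify both arms, anchor the classifier on the vehicle arm, classify
    both.  Returns a dict with per-arm cell tables, the vehicle reference and
    both summaries."""
    v_nuclei, v_cells, _ = quantify_arm(vehicle_scenes, seg_params=seg_params)
    e_nuclei, e_cells, _ = quantify_arm(exposed_scenes, seg_params=seg_params)
    ref = build_vehicle_reference(v_nuclei)
    v_cells, v_summary = classify_cells(v_cells, ref, group="vehicle")
    e_cells, e_summary = classify_cells(e_cells, ref, group="exposed")
    return dict(
        vehicle_nuclei=v_nuclei, vehicle_cells=v_cells,
        exposed_nuclei=e_nuclei, exposed_cells=e_cells,
        reference=ref,
        vehicle_summary=v_summary, exposed_summary=e_summary,
    )


# --------------------------------------------------------------------------- #
# parameter-recovery benchmark
# --------------------------------------------------------------------------- #


def _child_seeds(seed: int, n: int) -> list[int]:
    return [int(s) for s in
            np.random.SeedSequence(seed).generate_state(n) % (2**31)]


def recover_morphometry(seed: int, n_scenes: int = 15, cells_per_scene: int = 40,
                        giant_fraction: float = 0.2, mnc_fraction: float = 0.1
                        ) -> dict:
    """Planted vs pipeline-recovered giant/MNC percentages."""
    vehicle_cfg = SceneConfig(n_cells=cells_per_scene, seed=seed)
    exposed_cfg = vehicle_cfg.replace(giant_fraction=giant_fraction,
                                      mnc_fraction=mnc_fraction)
    vehicle, exposed = generate_population(vehicle_cfg, exposed_cfg, n_scenes,
                                           master_seed=seed)
    res = classify_arms(vehicle, exposed)
    truth_cells = pd.concat([t.cells_frame() for _, t in exposed], ignore_index=True)
    return dict(
        planted_pct_giant=100.0 * giant_fraction,
        planted_pct_mnc=100.0 * mnc_fraction,
        truth_pct_giant=100.0 * truth_cells["is_giant_true"].mean(),
        truth_pct_mnc=100.0 * truth_cells["is_mnc_true"].mean(),
        recovered_pct_giant=res["exposed_summary"].pct_giant,
        recovered_pct_mnc=res["exposed_summary"].pct_mnc,
        vehicle_pct_giant=res["vehicle_summary"].pct_giant,
        n_exposed_cells=res["exposed_summary"].n_cells,
        n_vehicle_cells=res["vehicle_summary"].n_cells,
        result=res,
    )


def recover_translocation(seed: int, ratios=(1.0, 2.0, 4.0),
                          n_scenes: int = 2, cells_per_scene: int = 30,
                          noise: bool = True) -> dict:
    """Planted vs recovered nuclear:cytosolic ratios, one entry per ratio."""
    seeds = _child_seeds(seed, len(ratios) * n_scenes)
    out = {}
    i = 0
    for r in ratios:
        scenes = []
        for _ in range(n_scenes):
            cfg = SceneConfig(
                n_cells=cells_per_scene, marker_ratio=r, seed=seeds[i],
                poisson_noise=noise,
                gaussian_noise_sd=2.0 if noise else 0.0,
            )
            scenes.append(generate_scene(cfg))
            i += 1
        _, cells, _ = quantify_arm(scenes)
        measured = cells.loc[cells["ratio_defined"], "ratio"]
        out[r] = dict(
            planted=r,
            mean_recovered=float(measured.mean()),
            n_cells=int(len(measured)),
            rel_error=abs(float(measured.mean()) - r) / r,
        )
    return out


def recover_foci(seed: int, lam: float = 5.0, n_scenes: int = 4,
                 cells_per_scene: int = 25) -> dict:
    """Exact-count fraction on planted foci plus the spurious rate on blank
    nuclei.  Uses roomier nuclei (area mean 250 um^2) so that Poisson counts
    up to the upper tail can be planted well separated."""
    seeds = _child_seeds(seed, 2 * n_scenes)
    exact = 0
    total = 0
    for k in range(n_scenes):
        cfg = SceneConfig(n_cells=cells_per_scene, foci_lambda=lam,
                          vehicle_area_mean_um2=250.0, seed=seeds[k])
        stack, truth = generate_scene(cfg)
        flat = reduce_z(stack)
        labels = segment_nuclei(flat.channel("DAPI"))
        counts, _ = detect_foci(flat.channel("MARKER"), labels)
        for nuc in truth.nuclei:
            lbl = labels[int(round(nuc.center_yx[0])), int(round(nuc.center_yx[1]))]
            if lbl == 0:
                continue
            total += 1
            if int(counts.loc[lbl]) == nuc.foci_count:
                exact += 1
    spurious = 0
    blank_total = 0
    for k in range(n_scenes):
        cfg = SceneConfig(n_cells=cells_per_scene, foci_lambda=0.0,
                          vehicle_area_mean_um2=250.0, seed=seeds[n_scenes + k])
        stack, truth = generate_scene(cfg)
        flat = reduce_z(stack)
        labels = segment_nuclei(flat.channel("DAPI"))
        counts, _ = detect_foci(flat.channel("MARKER"), labels)
        spurious += int(counts.sum())
        blank_total += len(counts)
    return dict(
        exact_fraction=exact / total if total else float("nan"),
        n_nuclei=total,
        spurious_per_nucleus=spurious / blank_total if blank_total else float("nan"),
        n_blank_nuclei=blank_total,
    )


def recover_ddct(seed: int, folds=(0.5, 1.0, 2.0, 8.0), n_reps: int = 200,
                 ct_noise_sd: float = 0.2, n_replicates: int = 4) -> dict:
    """Fold-change recovery by 2^-ΔΔCt: exact at zero noise, mean absolute
    relative error across seeded repetitions at the stated Ct noise."""
    genes = [f"g{i}" for i in range(len(folds))]
    clean = generate_ct_table(genes, list(folds), n_replicates=n_replicates,
                              ct_noise_sd=0.0, seed=seed)
    summary, _ = ddct_fold_changes(clean)
    exact = {g: float(summary.set_index("gene").loc[g, "fold_change"])
             for g in genes}
    seeds = _child_seeds(seed, n_reps)
    errs = []
    for s in seeds:
        tbl = generate_ct_table(genes, list(folds), n_replicates=n_replicates,
                                ct_noise_sd=ct_noise_sd, seed=s)
        summ, _ = ddct_fold_changes(tbl)
        fc = summ.set_index("gene")["fold_change"]
        errs.extend(abs(fc[g] - f) / f for g, f in zip(genes, folds))
    return dict(
        zero_noise_folds={g: exact[g] for g in genes},
        planted_folds=dict(zip(genes, folds)),
        mean_abs_rel_error=float(np.mean(errs)),
        n_repetitions=n_reps,
    )


def recover_deg(seed: int, n_genes: int = 1000, n_deg: int = 50,
                planted_lfc: float = 1.0) -> dict:
    """DEG-filter recovery: planted DEGs retained, and exact set equality with
    an independent rule-by-rule application."""
    tbl = generate_gene_stats(n_genes, n_deg, planted_lfc=planted_lfc, seed=seed)
    res = deg_filter(tbl)
    planted = set(tbl.loc[tbl["is_planted_deg"], "gene_id"])

    # independent rule-by-rule oracle on the same table
    cpm_cols = [c for c in tbl.columns if c.startswith("cpm")]
    expressed = tbl[(tbl[cpm_cols] > 1.0).sum(axis=1) >= 2]
    adj = bh_adjust(expressed["pvalue"].tolist())
    keep = expressed[(np.asarray(adj) < 0.05)
                     & ((expressed["log2fc"] < -0.5) | (expressed["log2fc"] > 0.5))]
    oracle = set(keep["gene_id"])

    return dict(
        n_planted=n_deg,
        n_recovered_planted=len(res.degs & planted),
        n_retained=len(res.degs),
        n_up=len(res.up),
        n_down=len(res.down),
        oracle_set_equal=res.degs == oracle,
    )


def run_recover(seed: int = 1, quick: bool = False) -> dict:
    """Full parameter-recovery benchmark with pass/fail tolerance checks.

    ``quick`` shrinks scene counts for smoke runs; the default sizes are the
    benchmark's study conditions (>= 500 cells per arm for morphometry,
    >= 50 cells per planted ratio, >= 100 nuclei per foci condition).
    """
    seeds = _child_seeds(seed, 6)
    n_scenes = 4 if quick else 15
    morpho = recover_morphometry(seeds[0], n_scenes=n_scenes)
    morpho.pop("result")
    transloc = recover_translocation(seeds[1],
                                     n_scenes=1 if quick else 2,
                                     cells_per_scene=30 if quick else 30)
    foci = recover_foci(seeds[2], n_scenes=1 if quick else 4)
    ddct = recover_ddct(seeds[3], n_reps=20 if quick else 200)
    deg = recover_deg(seeds[4])
    conversion = molar_to_mass_conc(1.0)

    checks = {
        "gc_within_3pts": abs(morpho["recovered_pct_giant"]
                              - morpho["planted_pct_giant"]) <= 3.0,
        "mnc_within_2pts": abs(morpho["recovered_pct_mnc"]
                               - morpho["planted_pct_mnc"]) <= 2.0,
        "vehicle_gc_below_1pct": morpho["vehicle_pct_giant"] <= 1.0,
        "ratios_within_10pct": all(v["rel_error"] <= 0.10
                                   for v in transloc.values()),
        "foci_exact_ge_95pct": foci["exact_fraction"] >= 0.95,
        "foci_spurious_le_0.05": foci["spurious_per_nucleus"] <= 0.05,
        "ddct_mare_le_15pct": ddct["mean_abs_rel_error"] <= 0.15,
        "deg_all_planted_recovered": deg["n_recovered_planted"] == deg["n_planted"],
        "deg_oracle_set_equal": bool(deg["oracle_set_equal"]),
        "conversion_75ppb": math.isclose(conversion, 74.92, rel_tol=1e-12),
    }
    return dict(
        seed=seed,
        morphometry=morpho,
        translocation={str(k): v for k, v in transloc.items()},
        foci=foci,
        ddct=ddct,
        deg=deg,
        arsenite_1uM_ug_per_L=conversion,
        checks=checks,
        all_passed=all(checks.values()),
    )
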