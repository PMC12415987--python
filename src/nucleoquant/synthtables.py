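"""Synthetic tabular fixtures: qPCR Ct tables with planted fold changes and
per-gene statistics tables with planted differentially expressed genes."""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np
import pandas as pd


def generate_ct_table(genes: Sequence[str], fold_changes: Sequence[float],
                      n_replicates: int = 4, ct_noise_sd: float = 0.0,
                      seed: int = 0, reference_gene: str = "GAPDH",
                      target_baseline_ct: float = 25.0,
                      reference_baseline_ct: float = 18.0) -> pd.DataFrame:
    """Ct table for vehicle and exposed arms with known fold changes.

    The exposed-arm Ct for gene g is shifted by −log2(fold_change_g) before
    noise, so the planted 2^−ΔΔCt equals the requested fold change exactly at
    zero noise.  The reference gene is appended automatically (fold change 1)
    when absent.
    """
    genes = list(genes)
    fold_changes = list(fold_changes)
    if len(genes) != len(fold_changes):
        raise ValueError("one fold change per gene required")
    if any(f <= 0 for f in fold_changes):
        raise ValueError("fold changes must be positive")
    if n_replicates < 1:
        raise ValueError("n_replicates must be positive")
    if ct_noise_sd < 0:
        raise ValueError("ct_noise_sd must be non-negative")
    if reference_gene in genes:
        if fold_changes[genes.index(reference_gene)] != 1.0:
            raise ValueError("reference gene must have fold change 1")
    else:
        genes.append(reference_gene)
        fold_changes.append(1.0)

    rng = np.random.default_rng(seed)
    rows = []
    for group in ("vehicle", "exposed"):
        for rep in range(1, n_replicates + 1):
            sample = f"{group}_{rep}"
            for gene, fc in zip(genes, fold_changes):
                base = (reference_baseline_ct if gene == reference_gene
                        else target_baseline_ct)
                ct = base
                if group == "exposed":
                    ct -= math.log2(fc)
                if ct_noise_sd > 0:
                    ct += rng.normal(0.0, ct_noise_sd)
                rows.append(dict(sample_id=sample, group=group, gene=gene, ct=ct))
    return pd.DataFrame(rows, columns=["sample_id", "group", "gene", "ct"])


def generate_gene_stats(n_genes: int, n_deg: int, planted_lfc: float = 1.0,
                        seed: int = 0, n_samples: int = 6,
                        planted_p: float = 1e-6,
                        low_expression_fraction: float = 0.1) -> pd.DataFrame:
    """Per-gene table exercising every rule of the DEG filter.

    Planted DEGs carry |log2FC| = |planted_lfc| (alternating sign), p =
    ``planted_p`` and well-expressed CPM.  Null genes carry small log2FC
    (inside ±0.5) and uniform p-values; ``low_expression_fraction`` of the
    null genes get CPM < 1 in every sample so the expression rule fires.
    """
    if n_deg > n_genes:
        raise ValueError("n_deg cannot exceed n_genes")
    if n_deg > 0 and abs(planted_lfc) <= 0.5:
        raise ValueError("|planted_lfc| must exceed 0.5 for planted DEGs "
                         "to be recoverable")
    rng = np.random.default_rng(seed)
    gene_ids = [f"gene_{i:05d}" for i in range(n_genes)]
    is_planted = np.zeros(n_genes, dtype=bool)
    if n_deg:
        is_planted[rng.choice(n_genes, size=n_deg, replace=False)] = True

    lfc = rng.normal(0.0, 0.15, size=n_genes).clip(-0.45, 0.45)
    signs = np.where(np.arange(n_genes) % 2 == 0, 1.0, -1.0)
    lfc[is_planted] = (abs(planted_lfc) * signs)[is_planted]

    p = rng.uniform(0.0, 1.0, size=n_genes)
    p[is_planted] = planted_p

    cpm = rng.lognormal(mean=math.log(30.0), sigma=0.8, size=(n_genes, n_samples))
    null_idx = np.flatnonzero(~is_planted)
    n_low = int(round(low_expression_fraction * len(null_idx)))
    low_idx = rng.choice(null_idx, size=n_low, replace=False) if n_low else []
    cpm[low_idx] = rng.uniform(0.05, 0.9, size=(len(low_idx), n_samples))

    df = pd.DataFrame({"gene_id": gene_ids})
    for j in range(n_samples):
        df[f"cpm_{j + 1}"] = cpm[:, j]
    df["log2fc"] = lfc
    df["pvalue"] = p
    df["is_planted_deg"] = is_planted
    return df
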