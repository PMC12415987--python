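"""Tabular read-outs: viability, 2^-ΔΔCt, cytokine normalization, the DEG
filter with an in-house Benjamini–Hochberg step-up, unit conversion, and
group comparisons.

The DEG definition is the three printed rules, all strict inequalities:
CPM > 1 in at least two samples, BH-adjusted p < 0.05, and |log2 fold
change| > 0.5.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

ARSENIC_MOLAR_MASS = 74.92  # g/mol, elemental As
SODIUM_ARSENITE_MOLAR_MASS = 129.91  # g/mol, NaAsO2


def viability_percent(live: int, dead: int) -> float:
    """Percentage of live cells out of all counted cells."""
    if live < 0 or dead < 0:
        raise ValueError("counts must be non-negative")
    total = live + dead
    if total == 0:
        raise ValueError("live + dead must be positive")
    return 100.0 * live / total


# --------------------------------------------------------------------------- #
# relative expression
# --------------------------------------------------------------------------- #


def ddct_fold_changes(table: pd.DataFrame, reference_gene: str = "GAPDH",
                      vehicle_label: str = "vehicle",
                      exposed_label: str = "exposed"):
    """Relative expression by the 2^-ΔΔCt method.

    ``table`` has columns ``sample_id, group, gene, ct``.  Per sample,
    ΔCt = Ct_gene − Ct_reference; ΔΔCt = mean ΔCt(exposed) − mean
    ΔCt(vehicle); fold change = 2^−ΔΔCt.  Per-replicate relative expressions
    2^−(ΔCt_i − mean ΔCt_vehicle) are returned alongside for dispersion.

    Returns ``(summary, per_replicate)`` DataFrames.
    """
    required = {"sample_id", "group", "gene", "ct"}
    if not required.issubset(table.columns):
        raise ValueError(f"table must have columns {sorted(required)}")
    ref = table[table["gene"] == reference_gene].set_index("sample_id")["ct"]
    samples = table["sample_id"].unique()
    missing = [s for s in samples if s not in ref.index]
    if missing:
        raise ValueError(f"samples missing reference-gene Ct: {missing}")

    work = table[table["gene"] != reference_gene].copy()
    work["delta_ct"] = work["ct"] - work["sample_id"].map(ref)

    rows = []
    rep_rows = []
    for gene, sub in work.groupby("gene", sort=True):
        veh = sub[sub["group"] == vehicle_label]["delta_ct"]
        exp = sub[sub["group"] == exposed_label]["delta_ct"]
        if veh.empty or exp.empty:
            raise ValueError(f"gene {gene!r} absent from one group")
        ddct = float(exp.mean() - veh.mean())
        rel = 2.0 ** -(sub["delta_ct"] - veh.mean())
        rep = sub[["sample_id", "group"]].copy()
        rep["gene"] = gene
        rep["rel_expr"] = rel
        rep_rows.append(rep)
        exp_rel = rel[sub["group"] == exposed_label]
        rows.append(dict(
            gene=gene,
            n_vehicle=int(len(veh)),
            n_exposed=int(len(exp)),
            delta_delta_ct=ddct,
            fold_change=2.0**-ddct,
            fold_sd=float(exp_rel.std(ddof=1)) if len(exp_rel) > 1 else np.nan,
        ))
    summary = pd.DataFrame(rows)
    per_replicate = pd.concat(rep_rows, ignore_index=True)
    return summary, per_replicate


# --------------------------------------------------------------------------- #
# multiple testing and the DEG filter
# --------------------------------------------------------------------------- #


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, in input order.

    adj_i = min over j >= i (in the ascending ordering) of m * p_(j) / j,
    clipped at 1.
    """
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value list")
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    adj_sorted = np.minimum(adj_sorted, 1.0)
    adj = np.empty(m)
    adj[order] = adj_sorted
    return adj


@dataclass
class DegResult:
    table: pd.DataFrame  # input plus passes_expression, adj_pvalue, is_deg, direction

    @property
    def degs(self) -> set:
        return set(self.table.loc[self.table["is_deg"], "gene_id"])

    @property
    def up(self) -> set:
        return set(self.table.loc[
            self.table["is_deg"] & (self.table["direction"] == "up"), "gene_id"])

    @property
    def down(self) -> set:
        return set(self.table.loc[
            self.table["is_deg"] & (self.table["direction"] == "down"), "gene_id"])


def deg_filter(table: pd.DataFrame, cpm_min: float = 1.0, min_samples: int = 2,
               alpha: float = 0.05, lfc_cut: float = 0.5,
               bh_within_expressed: bool = True) -> DegResult:
    """Differentially-expressed-gene filter.

    Expects columns ``gene_id``, ``log2fc``, ``pvalue`` and one ``cpm_*``
    column per sample.  Rules (all strict): CPM > ``cpm_min`` in at least
    ``min_samples`` samples; BH-adjusted p < ``alpha``; log2FC < −``lfc_cut``
    or > ``lfc_cut``.  By default BH runs over the genes passing the
    expression rule (the family actually tested downstream of an expression
    filter); ``bh_within_expressed=False`` corrects over all genes instead.
    """
    cpm_cols = [c for c in table.columns if c.startswith("cpm")]
    if not cpm_cols:
        raise ValueError("table needs cpm_* columns")
    out = table.copy()
    cpm = out[cpm_cols].to_numpy(dtype=float)
    out["passes_expression"] = (cpm > cpm_min).sum(axis=1) >= min_samples

    out["adj_pvalue"] = np.nan
    if bh_within_expressed:
        mask = out["passes_expression"].to_numpy()
        if mask.any():
            out.loc[mask, "adj_pvalue"] = bh_adjust(out.loc[mask, "pvalue"])
    else:
        out["adj_pvalue"] = bh_adjust(out["pvalue"])

    lfc = out["log2fc"]
    out["is_deg"] = (
        out["passes_expression"]
        & (out["adj_pvalue"] < alpha)
        & ((lfc < -lfc_cut) | (lfc > lfc_cut))
    )
    out["direction"] = np.where(lfc > lfc_cut, "up",
                                np.where(lfc < -lfc_cut, "down", "ns"))
    out.loc[~out["is_deg"], "direction"] = np.where(
        out.loc[~out["is_deg"], "direction"] == "ns", "ns", "filtered")
    out.loc[~out["is_deg"], "direction"] = "ns"
    return DegResult(table=out)


# --------------------------------------------------------------------------- #
# unit conversions and normalizations
# --------------------------------------------------------------------------- #


def normalize_cytokine(conc_pg_ml: float, volume_ml: float,
                       cell_count: int) -> float:
    """Secreted amount per 10^6 cells: conc x volume / cells x 1e6 (pg)."""
    if conc_pg_ml < 0:
        raise ValueError("concentration must be non-negative")
    if volume_ml <= 0:
        raise ValueError("volume must be positive")
    if cell_count <= 0:
        raise ValueError("cell count must be positive")
    return conc_pg_ml * volume_ml / cell_count * 1e6


def molar_to_mass_conc(concentration_um: float,
                       molar_mass_g_mol: float = ARSENIC_MOLAR_MASS) -> float:
    """Micromolar -> mass concentration in ug/L (numerically ppb for dilute
    aqueous solutions): 1 umol/L x M g/mol = M ug/L.

    The default molar mass is elemental arsenic (74.92 g/mol), under which
    1 uM arsenite corresponds to ~75 ug/L of arsenic.
    """
    if concentration_um <= 0 or molar_mass_g_mol <= 0:
        raise ValueError("concentration and molar mass must be positive")
    return concentration_um * molar_mass_g_mol


# --------------------------------------------------------------------------- #
# group comparisons
# --------------------------------------------------------------------------- #


@dataclass
class GroupComparison:
    statistic: float
    pvalue: float
    method: str
    group_sizes: tuple[int, ...]
    posthoc: pd.DataFrame | None = None


def compare_groups(a: Sequence[float], b: Sequence[float], *rest,
                   method: str = "t_unpaired") -> GroupComparison:
    """Two-group or multi-group comparison.

    ``t_unpaired``: two-tailed unpaired Student's t-test (pooled variance);
    ``welch_t``: the Welch-corrected variant; ``anova_tukey``: one-way ANOVA
    across >= 3 groups with Tukey HSD post-hoc comparisons.
    """
    groups = [np.asarray(list(g), dtype=float) for g in (a, b, *rest)]
    if method in ("t_unpaired", "welch_t"):
        if rest:
            raise ValueError("t-tests take exactly two groups")
        if any(len(g) < 2 for g in groups):
            raise ValueError("each group needs >= 2 values")
        res = sps.ttest_ind(groups[0], groups[1],
                            equal_var=(method == "t_unpaired"))
        return GroupComparison(
            statistic=float(res.statistic), pvalue=float(res.pvalue),
            method=method, group_sizes=tuple(len(g) for g in groups),
        )
    if method == "anova_tukey":
        if len(groups) < 3:
            raise ValueError("ANOVA path needs >= 3 groups")
        if any(len(g) < 2 for g in groups):
            raise ValueError("each group needs >= 2 values")
        f = sps.f_oneway(*groups)
        tk = sps.tukey_hsd(*groups)
        rows = []
        for i in range(len(groups)):
            for j in range(i + 1, len(groups)):
                rows.append(dict(
                    group_a=i, group_b=j,
                    statistic=float(tk.statistic[i, j]),
                    p_adj=float(tk.pvalue[i, j]),
                ))
        return GroupComparison(
            statistic=float(f.statistic), pvalue=float(f.pvalue),
            method=method, group_sizes=tuple(len(g) for g in groups),
            posthoc=pd.DataFrame(rows),
        )
    raise ValueError(f"unknown method {method!r}")
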