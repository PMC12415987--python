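"""Tabular statistics: viability, ΔΔCt, BH, the DEG filter, normalizations
and group comparisons."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from nucleoquant import (
    bh_adjust,
    compare_groups,
    ddct_fold_changes,
    deg_filter,
    generate_ct_table,
    generate_gene_stats,
    molar_to_mass_conc,
    normalize_cytokine,
    viability_percent,
)


# --------------------------------------------------------------------------- #
# viability
# --------------------------------------------------------------------------- #


@pytest.mark.parametrize("live, dead, expected",
                         [(50, 50, 50.0), (0, 10, 0.0), (75, 25, 75.0)])
def test_viability_percent(live, dead, expected):
    assert viability_percent(live, dead) == expected


def test_viability_zero_total_errors():
    with pytest.raises(ValueError):
        viability_percent(0, 0)


# --------------------------------------------------------------------------- #
# delta-delta-Ct
# --------------------------------------------------------------------------- #


def _ct_rows(gene_cts):
    rows = []
    for sample, group, gene, ct in gene_cts:
        rows.append(dict(sample_id=sample, group=group, gene=gene, ct=ct))
    return pd.DataFrame(rows)


def test_ddct_hand_example():
    table = _ct_rows([
        ("v1", "vehicle", "IL6", 26.0), ("v1", "vehicle", "GAPDH", 20.0),
        ("v2", "vehicle", "IL6", 26.0), ("v2", "vehicle", "GAPDH", 20.0),
        ("e1", "exposed", "IL6", 25.0), ("e1", "exposed", "GAPDH", 20.0),
        ("e2", "exposed", "IL6", 25.0), ("e2", "exposed", "GAPDH", 20.0),
    ])
    summary, reps = ddct_fold_changes(table)
    assert summary.loc[0, "delta_delta_ct"] == pytest.approx(-1.0)
    assert summary.loc[0, "fold_change"] == pytest.approx(2.0)
    veh_reps = reps[reps["group"] == "vehicle"]["rel_expr"]
    assert veh_reps.mean() == pytest.approx(1.0)


def test_ddct_null_and_generator_exactness():
    null = generate_ct_table(["a", "b"], [1.0, 1.0], n_replicates=3,
                             ct_noise_sd=0.0, seed=0)
    summary, _ = ddct_fold_changes(null)
    assert np.allclose(summary["fold_change"], 1.0)

    planted = generate_ct_table(["a", "b", "c"], [0.5, 2.0, 8.0],
                                n_replicates=4, ct_noise_sd=0.0, seed=1)
    summary, _ = ddct_fold_changes(planted)
    got = summary.set_index("gene")["fold_change"]
    assert got["a"] == pytest.approx(0.5)
    assert got["b"] == pytest.approx(2.0)
    assert got["c"] == pytest.approx(8.0)


def test_ct_noise_free_exposed_shifted_by_log2_fold():
    tbl = generate_ct_table(["g"], [2.0], n_replicates=2, ct_noise_sd=0.0)
    g = tbl[tbl["gene"] == "g"]
    veh = g[g["group"] == "vehicle"]["ct"].unique()
    exp = g[g["group"] == "exposed"]["ct"].unique()
    assert exp == pytest.approx(veh - 1.0)


def test_ddct_missing_reference_errors():
    table = _ct_rows([("v1", "vehicle", "IL6", 26.0),
                      ("e1", "exposed", "IL6", 25.0)])
    with pytest.raises(ValueError, match="reference"):
        ddct_fold_changes(table)


def test_ddct_gene_absent_from_one_group_errors():
    table = _ct_rows([
        ("v1", "vehicle", "IL6", 26.0), ("v1", "vehicle", "GAPDH", 20.0),
        ("e1", "exposed", "GAPDH", 20.0),
    ])
    with pytest.raises(ValueError, match="absent"):
        ddct_fold_changes(table)


def test_ct_table_generator_validations():
    with pytest.raises(ValueError):
        generate_ct_table(["a"], [0.0])
    with pytest.raises(ValueError):
        generate_ct_table(["a", "GAPDH"], [2.0, 3.0])


# --------------------------------------------------------------------------- #
# Benjamini-Hochberg
# --------------------------------------------------------------------------- #


def _bh_oracle(pvalues):
    """Literal step-up definition: adj_i = min_{j >= rank(i)} m p_(j) / j."""
    m = len(pvalues)
    order = sorted(range(m), key=lambda i: pvalues[i])
    adj = [0.0] * m
    for pos, i in enumerate(order):
        candidates = [m * pvalues[order[j]] / (j + 1) for j in range(pos, m)]
        adj[i] = min(1.0, min(candidates))
    return adj


def test_bh_single_value_unchanged():
    assert bh_adjust([0.03]) == pytest.approx([0.03])


def test_bh_textbook_example():
    assert bh_adjust([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)


def test_bh_matches_exhaustive_oracle_and_statsmodels(rng):
    from statsmodels.stats.multitest import multipletests

    for _ in range(200):
        n = int(rng.integers(1, 11))
        p = rng.random(n)
        ours = bh_adjust(p)
        assert ours == pytest.approx(_bh_oracle(list(p)), rel=1e-12)
        sm = multipletests(p, method="fdr_bh")[1]
        assert ours == pytest.approx(sm, rel=1e-9)


@settings(max_examples=100, deadline=None, derandomize=True)
@given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=10))
def test_bh_adjusted_never_below_raw(p):
    adj = bh_adjust(p)
    assert np.all(adj >= np.asarray(p) - 1e-15)
    assert np.all(adj <= 1.0)


def test_bh_rejects_invalid():
    with pytest.raises(ValueError):
        bh_adjust([])
    with pytest.raises(ValueError):
        bh_adjust([0.5, 1.5])


# --------------------------------------------------------------------------- #
# DEG filter
# --------------------------------------------------------------------------- #


def _gene_row(gene_id, cpms, log2fc, pvalue):
    row = {"gene_id": gene_id, "log2fc": log2fc, "pvalue": pvalue}
    for j, c in enumerate(cpms, start=1):
        row[f"cpm_{j}"] = c
    return row


def test_low_expression_excluded_regardless_of_significance():
    table = pd.DataFrame([
        _gene_row("low", [0.5, 0.5, 0.5], 3.0, 1e-9),
        _gene_row("ok", [10, 10, 10], 3.0, 1e-9),
    ])
    res = deg_filter(table)
    assert res.degs == {"ok"}


def test_lfc_boundary_is_strict():
    table = pd.DataFrame([
        _gene_row("edge", [10, 10, 10], 0.5, 1e-9),
        _gene_row("past", [10, 10, 10], 0.5000001, 1e-9),
    ])
    res = deg_filter(table)
    assert res.degs == {"past"}
    assert res.up == {"past"} and res.down == set()


def test_planted_table_recovery_and_rule_by_rule_oracle():
    table = generate_gene_stats(1000, 50, planted_lfc=1.0, seed=4)
    res = deg_filter(table)
    planted = set(table.loc[table["is_planted_deg"], "gene_id"])
    assert planted <= res.degs

    cpm_cols = [c for c in table.columns if c.startswith("cpm")]
    expressed = table[(table[cpm_cols] > 1.0).sum(axis=1) >= 2]
    adj = bh_adjust(expressed["pvalue"].tolist())
    oracle = set(expressed.loc[
        (np.asarray(adj) < 0.05)
        & ((expressed["log2fc"] < -0.5) | (expressed["log2fc"] > 0.5)),
        "gene_id"])
    assert res.degs == oracle


def test_null_table_retains_almost_nothing():
    table = generate_gene_stats(500, 0, seed=8)
    res = deg_filter(table)
    # BH at alpha 0.05 on uniform p-values with the |log2FC| gate closed
    assert len(res.degs) == 0


def test_gene_stats_generator_validations():
    with pytest.raises(ValueError):
        generate_gene_stats(10, 20)
    with pytest.raises(ValueError):
        generate_gene_stats(10, 2, planted_lfc=0.3)


# --------------------------------------------------------------------------- #
# normalizations and conversions
# --------------------------------------------------------------------------- #


def test_cytokine_normalization():
    assert normalize_cytokine(100.0, 1.0, 10**6) == pytest.approx(100.0)
    assert normalize_cytokine(100.0, 1.0, 2 * 10**6) == pytest.approx(50.0)
    assert normalize_cytokine(483.6, 2.0, 5 * 10**5) == pytest.approx(1934.4)
    with pytest.raises(ValueError):
        normalize_cytokine(1.0, 1.0, 0)


def test_molar_conversion_values_and_linearity():
    assert molar_to_mass_conc(1.0) == pytest.approx(74.92)
    assert molar_to_mass_conc(0.5, 100.0) == pytest.approx(50.0)
    assert molar_to_mass_conc(1.0, 1.0) == pytest.approx(1.0)
    a = molar_to_mass_conc(2.0, 74.92)
    assert a == pytest.approx(2 * molar_to_mass_conc(1.0, 74.92))
    with pytest.raises(ValueError):
        molar_to_mass_conc(-1.0)


# --------------------------------------------------------------------------- #
# group comparisons
# --------------------------------------------------------------------------- #


def test_identical_groups_null_result():
    res = compare_groups([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
    assert res.statistic == pytest.approx(0.0)
    assert res.pvalue == pytest.approx(1.0)


def test_two_sided_p_symmetric_in_group_order(rng):
    a = list(rng.normal(0, 1, 5))
    b = list(rng.normal(1, 2, 7))
    assert compare_groups(a, b).pvalue == pytest.approx(
        compare_groups(b, a).pvalue)
    assert compare_groups(a, b, method="welch_t").pvalue == pytest.approx(
        compare_groups(b, a, method="welch_t").pvalue)


def test_t_tests_match_textbook_formulas():
    from scipy import stats as sps

    a = [1.0, 2.0, 3.0]
    b = [1.0, 2.0, 3.0, 100.0]
    pooled = compare_groups(a, b)
    welch = compare_groups(a, b, method="welch_t")
    assert pooled.pvalue != pytest.approx(welch.pvalue)

    na, nb = len(a), len(b)
    va, vb = np.var(a, ddof=1), np.var(b, ddof=1)
    sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
    t_pool = (np.mean(a) - np.mean(b)) / math.sqrt(sp2 * (1 / na + 1 / nb))
    p_pool = 2 * sps.t.sf(abs(t_pool), na + nb - 2)
    assert pooled.statistic == pytest.approx(t_pool, abs=1e-6)
    assert pooled.pvalue == pytest.approx(p_pool, abs=1e-6)

    se2 = va / na + vb / nb
    t_w = (np.mean(a) - np.mean(b)) / math.sqrt(se2)
    df_w = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    p_w = 2 * sps.t.sf(abs(t_w), df_w)
    assert welch.statistic == pytest.approx(t_w, abs=1e-6)
    assert welch.pvalue == pytest.approx(p_w, abs=1e-6)


def test_anova_tukey_path():
    res = compare_groups([1, 2, 3], [2, 3, 4], [10, 11, 12],
                         method="anova_tukey")
    assert res.pvalue < 0.01
    assert len(res.posthoc) == 3
    assert set(res.posthoc.columns) == {"group_a", "group_b", "statistic",
                                        "p_adj"}


def test_group_size_validation():
    with pytest.raises(ValueError):
        compare_groups([1.0], [1.0, 2.0])
    with pytest.raises(ValueError):
        compare_groups([1, 2], [3, 4], method="anova_tukey")
    with pytest.raises(ValueError):
        compare_groups([1, 2], [3, 4], [5, 6], method="t_unpaired")
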