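"""Tabular statistics: 2^-ΔΔCt fold changes, cytokine normalization, the DEG
filter with in-house Benjamini-Hochberg, and the dose unit conversion."""

from nucleoquant import (
    ddct_fold_changes,
    deg_filter,
    generate_ct_table,
    generate_gene_stats,
    molar_to_mass_conc,
    normalize_cytokine,
)

# qPCR: plant known fold changes, add realistic Ct noise, recover by ddCt
table = generate_ct_table(["IL6", "IL8", "TNFA"], [4.0, 2.0, 0.5],
                          n_replicates=4, ct_noise_sd=0.2, seed=1)
summary, _ = ddct_fold_changes(table)
print("2^-ddCt fold changes (planted 4.0 / 2.0 / 0.5):")
print(summary[["gene", "delta_delta_ct", "fold_change"]]
      .to_string(index=False))

# cytokine secretion per million cells
print(f"\n483.6 pg/mL in 2 mL from 5e5 cells -> "
      f"{normalize_cytokine(483.6, 2.0, 500_000):.1f} pg per 1e6 cells")

# DEG filter: CPM > 1 in >= 2 samples, BH adj p < 0.05, |log2FC| > 0.5
genes = generate_gene_stats(n_genes=1000, n_deg=50, planted_lfc=1.0, seed=2)
res = deg_filter(genes)
print(f"DEG filter: retained {len(res.degs)} of 1000 genes "
      f"({len(res.up)} up, {len(res.down)} down; 50 were planted)")

# the exposure dose in mass-concentration units
print(f"1 uM arsenite = {molar_to_mass_conc(1.0):.2f} ug/L arsenic "
      f"(~75 ppb)")
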