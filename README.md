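# nucleoquant

Quantification of arsenic-type nuclear phenotypes in fluorescence
microscopy, for toxicologists and cell biologists studying chronic
metal(loid) exposure of primary epithelial cultures (e.g. ovarian surface
and fallopian-tube cells). Chronic low-level arsenite (1 µM ≈ 75 µg/L
arsenic) drives the formation of giant cells and multinucleated cells,
NF-κB p65 nuclear translocation, and persistent γH2AX DNA-damage foci;
`nucleoquant` turns those observations into reproducible numbers, and ships
a ground-truthed synthetic-microscopy generator so every stage is testable
without any raw images.

## What it computes

**Giant / multinucleated cell (GC/MNC) classification.** Nuclei are
segmented from DAPI, measured (pixel-count area, Crofton perimeter), and
grouped into cells via the cell-body channel. With vehicle (control) nuclei
giving mean μ and standard deviation σ of area and perimeter, a cell is

- *giant* iff its **total** nuclear area `> μ_A + 3σ_A` **or** total
  perimeter `> μ_P + 3σ_P` (totals summed over all nuclei in the cell),
- *multinucleated* iff it contains more than one nucleus.

**Nucleocytoplasmic translocation.** Per cell, the cytosolic signal
intensity is

    (ID_cell − ID_nucleus) / (Area_cell − Area_nucleus)

with ID the integrated density (sum of marker intensities over a region);
the translocation score is the nuclear mean intensity divided by this
cytosolic intensity (>1 = nuclear enrichment, e.g. of p65).

**Focus counting.** Marker images are band-passed with a scale-normalised
Laplacian of Gaussian; foci are prominent maxima per nucleus, thresholded at
`prominence_k` robust SDs of the nucleus's background response.

**Tabular statistics.** Relative expression by 2^−ΔΔCt against a reference
gene (GAPDH); cytokine secretion normalized to pg per 10⁶ cells; a DEG
filter (CPM > 1 in ≥ 2 samples, Benjamini–Hochberg adjusted p < 0.05,
|log₂FC| > 0.5) with an in-house BH step-up; viability %; µM → µg/L
conversion; unpaired t (pooled or Welch) and ANOVA/Tukey comparisons.

**Synthetic scenes.** `generate_scene` renders DAPI / MARKER / CELLBODY
channels with Poisson–Gaussian camera noise and returns exact ground truth
(per-nucleus ellipses, planted giant/MNC flags, planted nuclear:cytosolic
ratio, planted Poisson focus counts), the oracle for every recovery test.

## Worked example

```python
from nucleoquant import SceneConfig, generate_population
from nucleoquant.pipeline import classify_arms

vehicle_cfg = SceneConfig(n_cells=40, seed=1)
exposed_cfg = vehicle_cfg.replace(giant_fraction=0.2, mnc_fraction=0.1)
vehicle, exposed = generate_population(vehicle_cfg, exposed_cfg, n_scenes=5)
res = classify_arms(vehicle, exposed)
ref = res["reference"]
print(f"vehicle reference: area {ref.mean_area:.1f} ± {ref.sd_area:.1f} µm²"
      f" -> giant above {ref.area_threshold:.1f} µm²")
for arm in ("vehicle_summary", "exposed_summary"):
    s = res[arm]
    print(f"{s.group}: {s.n_cells} cells, {s.pct_giant:.1f}% giant, "
          f"{s.pct_mnc:.1f}% multinucleated")
```

prints

```
vehicle reference: area 102.5 ± 10.3 µm² -> giant above 133.4 µm²
vehicle: 200 cells, 0.0% giant, 0.0% multinucleated
exposed: 200 cells, 26.5% giant, 13.5% multinucleated
```

The vehicle arm anchors the 3σ thresholds (and, containing no planted
giants, classifies at 0%); in the exposed arm the measured 26.5% giant /
13.5% multinucleated agree with this run's planted ground truth (26.0% /
13.5% — the generator draws flags per cell, so a 200-cell run fluctuates
around the configured 20% / 10%). `examples/` contains one short script per
capability (simulation, classification, translocation, foci, tabular
statistics), each printing the numbers it computes.

A thin CLI mirrors the library: `nucleoquant simulate`, `quantify`,
`recover`, and `stats {ddct,degfilter,convert}`.

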