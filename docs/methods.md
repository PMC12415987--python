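# Methods

## Scope and model

`nucleoquant` quantifies four imaging read-outs — giant-cell and
multinucleated-cell (GC/MNC) frequency, nuclear:cytosolic marker
translocation, focus counts per nucleus, and confluence — plus the tabular
statistics that accompany them in a chronic-exposure experiment (2^−ΔΔCt,
cytokine normalization, DEG filtering, viability, group comparisons). The
imaging read-outs are all *vehicle-referenced or ratio-based*: none depends
on absolute intensity calibration, which is what makes them recoverable
from synthetic data with planted truth.

## The GC/MNC classifier

Nuclei come from the DAPI channel: Gaussian smoothing (σ = 2 px), Otsu
threshold (a fixed threshold is selectable), hole filling, optional
distance-transform watershed split, minimum-area filter (50 px²), and
border exclusion. The split stage smooths the Euclidean distance transform
(σ = 2 px) before peak picking: the distance map of a single convex nucleus
has a ridge-shaped maximum whose endpoints would otherwise be read as two
seeds; smoothing collapses the ridge to one peak while genuinely merged
nuclei keep two. Border-touching nuclei are excluded by default because a
truncated nucleus would bias the size reference downward.

Cells come from the cell-body channel: each connected foreground component
containing at least one nucleus is one cell, so several nuclei inside one
unbroken cell body remain a single (multinucleated) cell. A nucleus with no
cell-body support becomes a flagged one-nucleus cell equal to its own 10-px
dilation. Two physically touching cell bodies would merge under this rule —
acceptable at sub-confluent plating densities and for the generator's
non-overlapping geometry, a known limitation for confluent fields. Without
a cell-body channel every nucleus is its own cell and MNC status is
reported *unavailable* (not zero): multinucleation cannot be inferred from
DAPI alone.

The classifier takes the vehicle arm's uncensored nuclei, computes sample
mean and SD (n−1 denominator) of area and perimeter, and calls a cell giant
when its total nuclear area **or** total perimeter (summed over member
nuclei, exactly) strictly exceeds mean + 3 SD. The "3 SD above the mean"
reading is the standard upper-tail outlier convention; the literal
alternative (exceeding 3 SD as an absolute value) is preserved under
`rule="3sd_abs"` but classifies nearly every nucleus and is not the
default. Ties at the threshold (possible only when SD = 0) are not giant.
Percentages are computed over all classified cells pooled across scenes;
per-scene tables allow SEM across fields.

Perimeter uses the 4-direction Crofton estimator (scikit-image
`perimeter_crofton`), cross-checked in the tests against a marching-squares
contour length. Since the classifier is vehicle-referenced, only internal
consistency of the estimator matters, not its absolute bias.

## Translocation ratio

"Cytosolic signal intensity" is `(ID_cell − ID_nucleus) /
(Area_cell − Area_nucleus)` with ID the integrated density; the subtraction
form implies the first region is the **whole cell** (subtracting the
nuclear ID from an already-cytosolic region would double-count), so that is
the default; a strict mode averages over a supplied cytosol-only region
without subtraction. The translocation score is nuclear mean / cytosolic
intensity; a zero cytosolic intensity flags the ratio undefined (NaN) and
the cell is excluded from group means with its count reported. When no cell
mask exists, a 10-px dilation annulus clipped at neighbouring nuclei stands
in for the cell region — the standard translocation-assay fallback. The
ratio is invariant to global intensity scaling and, with ground-truth
masks and no noise, recovers the planted value exactly.

## Focus detection

The marker image is band-passed with a scale-normalised Laplacian of
Gaussian (σ = 2 px, matching diffraction-limited spots of ~1.5 px SD at
0.5 µm/px). Per nucleus, foci are maxima of the response with topographic
prominence (h-maxima) of at least `prominence_k = 5` robust SDs of the
background response, and absolute response above the per-nucleus median
plus the same margin; maxima closer than 3 px are merged in favour of the
stronger.

Two design points deserve explanation. First, the background response SD is
*not* estimated as the MAD of the in-nucleus response: at realistic focus
loads (λ ≈ 5) the foci's own band-pass response — positive cores plus
negative rings — covers most of the nuclear interior and inflates any
quantile-based scale estimate to the point of rejecting every true focus.
Instead the nucleus's camera noise is estimated in the intensity domain
with a median-based 3×3 second-difference estimator (blind to structure
smoother than ~2 px, foci included) and propagated through the LoG
filter's L2 norm; the per-nucleus median of the response still supplies the
offset, so the threshold remains local and offset-robust. Second, plain
local maxima produce ghost peaks at the centroid of three or more
clustered foci, where overlapping skirts sum to a genuine local maximum;
requiring topographic prominence removes these without touching resolved
foci. Peaks are searched inside the nucleus eroded by ceil(2σ)+1 px so the
band-pass edge response at the nuclear rim cannot register as a focus.

## Tabular statistics

- **2^−ΔΔCt:** per sample ΔCt = Ct_gene − Ct_reference; ΔΔCt = mean
  ΔCt(exposed) − mean ΔCt(vehicle); fold = 2^−ΔΔCt. Replicate dispersion is
  summarized by per-replicate folds 2^−(ΔCt_i − mean ΔCt_vehicle); no
  error-propagation scheme is imposed beyond that.
- **Benjamini–Hochberg** is implemented in-house as the step-up
  `adj_i = min_{j≥i} (m·p_(j)/j)` clipped at 1, and is cross-checked in the
  tests against both an exhaustive oracle and statsmodels.
- **DEG filter:** all three rules are strict inequalities (CPM > 1 in ≥ 2
  samples; adjusted p < 0.05; log₂FC < −0.5 or > 0.5). BH is applied to the
  genes passing the expression rule — the family actually tested downstream
  of an expression filter — with a flag to correct over all genes instead.
- **Cytokine normalization** reports pg per 10⁶ cells
  (conc × volume / cells × 10⁶).
- **Unit conversion:** 1 µmol/L × M g/mol = M µg/L; the default molar mass
  is elemental arsenic (74.92 g/mol), under which 1 µM arsenite ≈ 75 µg/L
  (≈ 75 ppb in dilute aqueous solution). The NaAsO₂ formula mass (129.91)
  is selectable.
- **Group comparisons** delegate to scipy (unpaired t with pooled or Welch
  variance, one-way ANOVA with Tukey HSD).

## The synthetic-data generator

The generator emulates fixed, DAPI-stained cultures at 0.5 µm/px: vehicle
nuclear areas are log-normal (mean 100 µm², CV 0.1 — strictly positive and
right-skewed like real nuclei; no measured distribution was available, so
these are stated defaults, not literature values), nuclei are near-round
ellipses (axis ratio 0.85–1), cell bodies are disks with a cytosolic
margin, and camera noise is Poisson shot noise followed by additive
Gaussian read noise (SD 2 counts) per z-plane. Giant cells scale the linear
nuclear radius by 2 (≈ 4× area), guaranteeing clear separation from the
vehicle 3σ threshold at the default CV. Multinucleated cells carry 2–4
nuclei splitting the cell's total nuclear content nearly evenly (Dirichlet
weights), placed without overlap inside one body.

Giant and multinucleated flags are drawn with **maximal overlap**: the
marginal fractions are honoured exactly, and MNCs nest inside the giant
compartment whenever `mnc_fraction ≤ giant_fraction`. This is deliberate:
under the summation rule, any cell with two or more normal-sized nuclei
exceeds the vehicle perimeter threshold (summed perimeter grows like √n),
so a "multinucleated but not giant" population is not realizable under the
classifier's own definition — and in arsenic-exposed cultures MNCs are
observed as a subset of giant cells, consistent with an
endoreplication/failed-cytokinesis origin.

The marker channel is rendered with exact level ratios (cytosol at a fixed
level, nuclei at `marker_ratio` times it), so with noise off the planted
ratio is recovered exactly. Foci are isotropic Gaussian spots (SD 1.5 px)
with peak amplitude 6× the cytosolic level (≥ 5× keeps detection
unambiguous while still exercising the detector); counts are Poisson per
nucleus and centers are placed by best-candidate sampling, at least
~6 px apart (best effort) and clear of the nuclear rim by the detection
band plus the spot extent. Per-scene seeds derive from a master seed via
`numpy.random.SeedSequence`, so any scene regenerates independently of
order.

What the generator does **not** emulate: optical point-spread blur beyond
Gaussian foci, true 3D structure (z-stacks are repeated planes with
independent noise), uneven illumination, touching or overlapping cells,
debris, and intensity heterogeneity within compartments. Passing recovery
tests therefore demonstrates the correctness of the measurement chain under
the stated noise model, not robustness to every artefact of real
microscopy; the segmentation parameters are exposed precisely because real
data will need retuning.

## Benchmark sizes and numerical choices

The recovery benchmark (`run_recover`, also behind `scripts/acceptance.py`)
uses 15 scenes × 40 cells per arm (600 cells/arm) for GC/MNC recovery, 60
cells per planted translocation ratio, 4 scenes of 25 cells at area mean
250 µm² per foci condition (roomier nuclei let upper-tail Poisson counts be
planted well separated), 200 repetitions of 4-replicate Ct tables at noise
SD 0.2, and one 1000-gene table with 50 planted DEGs. CSV output uses
`%.17g` floats and a correctly-rounded reader (`read_table`) so numeric
fields round-trip at full double precision. All label maps are compact
1..N; connectivity is 8 for foreground objects. Degenerate inputs are
defined rather than fatal: empty images yield empty label maps, an empty
cell table yields an n = 0 summary, SD = 0 references warn and make the
threshold equal the mean (ties not giant).
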