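"""Nuclear:cytosolic translocation ratio (NF-κB p65 style read-out).

Scenes are planted with a known nuclear:cytosolic marker ratio; the pipeline
segments nuclei and cell bodies and recovers the ratio per cell via the
cytosolic-intensity formula
(ID_cell - ID_nucleus) / (Area_cell - Area_nucleus).
"""

from nucleoquant import SceneConfig, generate_scene, quantify_scene

for planted in (1.0, 2.0, 4.0):
    cfg = SceneConfig(n_cells=30, marker_ratio=planted, seed=int(10 * planted))
    stack, _ = generate_scene(cfg)
    res = quantify_scene(stack)
    measured = res.cells.loc[res.cells.ratio_defined, "ratio"]
    print(f"planted ratio {planted:.1f} -> recovered "
          f"{measured.mean():.3f} +- {measured.std():.3f} "
          f"(n = {len(measured)} cells)")
# A ratio above 1 means the marker is enriched in the nucleus relative to
# the cytosol, i.e. nuclear translocation.
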