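"""Regional multispectral images: project electrodes, interpolate band maps.

Electrodes are mapped to the plane with the azimuthal equidistant projection
(vertex at the origin, nose up), each band is min-max normalized over the
region and interpolated with the Clough-Tocher scheme onto a shared 40x40
grid, and the three band maps become the R (theta), G (alpha), B (beta)
channels of a color image.
"""

from pathlib import Path

from eegfusion import (
    CohortSpec, PipelineConfig, default_montage, generate_cohort, project_aep,
    save_png, subject_images,
)

recordings, _, _ = generate_cohort(CohortSpec(n_per_class=2, seed=5))
montage = default_montage()

proj = project_aep(montage, ["Cz", "Fpz", "T7"])
for label, (u, v) in zip(proj.source_labels, proj.coords2d):
    print(f"{label:>4s} -> (u={u:+.3f}, v={v:+.3f})")
print("Cz (the vertex) projects to the origin; radius = great-circle distance.")

regional, fused = subject_images(recordings[0], montage, PipelineConfig())
out = Path("scratch/topomaps")
out.mkdir(parents=True, exist_ok=True)
for region, img in {**regional, "fused": fused}.items():
    save_png(img, out / f"{region}.png")
    inside = (img.pixels.sum(axis=2) > 0).mean()
    print(f"{region:>14s}: 40x40x3 image, {inside:.0%} of pixels inside the electrode hull")
print(f"PNGs written to {out}/ - the frontal image carries the theta hot spot.")
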