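# pancshell

Distance-shell quantification of heterologous cell interactions in 3D
light-sheet and 2D section images of the embryonic pancreas.

During pancreas development, endothelial and mesenchymal cells organize
tightly around the branched epithelial bud and its budding endocrine
clusters. Quantifying that organization from cleared whole-organ
light-sheet stacks is usually done with closed commercial tools (surface
rendering, spot detection, filament tracing, per-section cell counting).
`pancshell` is an open, tested reimplementation of that measurement chain
for biologists and image analysts who want the same numbers from scriptable
code:

* **Reference surfaces** — segment the epithelial (Ecad/Pdx1) or endocrine
  (glucagon) channel into a solid reference mask and export a triangle mesh.
* **Distance shells** — anisotropic Euclidean distance transform (EDT, in
  µm) of the surroundings; cells engulfed between branches count as
  distance 0 (direct contact). Layers are half-open: first cell layer
  `[0, 7.5) µm`, second `[7.5, 15) µm`, distant band `[15, 50) µm`.
* **Nuclear spots** — membrane-subtracted, anisotropy-corrected multiscale
  Laplacian-of-Gaussian detection (nuclear prior 5 µm xy / 7 µm z),
  dedup­lication, and DRAQ5±/Ecad±/ERG± classification into epithelial,
  endothelial and mesenchymal cells.
* **Per-spot measures** — distance records, first/second-layer fractions,
  cumulative frequency curves, and cell-type composition restricted to the
  0–15 µm shell.
* **Vessel morphometry** — VEcad mask → 3D skeleton graph → per-segment
  mean diameters from the interior EDT, proximity-filtered diameter
  histograms, and the vascular volume fraction of a shell.
* **Endocrine microenvironments** — glucagon⁺ clusters filtered at the
  eight-cell scale (3D volume > 67,700 µm³), then vascular volume fraction
  and mesenchymal density in each cluster's 0–15 and 15–50 µm shells.
* **2D sections** — the section-based counterpart (nuclear watershed,
  marker classification, 15 µm ROI, contact fractions, abundance pooled
  over sections every 30 µm), sharing the 3D boundary conventions.
* **Synthetic phantoms** — a seeded generator that builds a branched bud
  wrapped by tubular vessels with scattered, distance-structured nuclei,
  renders it with an anisotropic PSF and Poisson+Gaussian noise, and ships
  exact ground truth — the package's validation backbone.

Everything works in physical µm on anisotropic voxel grids (typical
light-sheet spacing (2, 1, 1) µm in z, y, x); voxel indices never cross the
API.

## Worked example

Generate a phantom and run the full 3D analysis on it:

```python
import pancshell as ps
from pancshell import phantom as ph

w = (0.68, 0.32, 0.0)  # first/second/distant shell weights
spec = ps.PhantomSpec(
    seed=7,
    nuclei=ph.NucleiParams(
        counts={"epithelial": 600, "endothelial": 500, "mesenchymal": 1500},
        shell_weights={"endothelial": w, "mesenchymal": w},
    ),
)
volume, truth = ph.make_phantom(spec)          # 300 µm ROI at (2,1,1) µm
results = ps.analyze_volume(volume, analyses=("proximity", "composition"))

for cls, fr in results["layer_fractions"].items():
    print(f"{cls}: first layer {fr['first']:.1f}%")
print({k: round(v, 1) for k, v in results["composition"].percentages.items()})
```

prints (seed 7):

```
endothelial: first layer 69.9%
mesenchymal: first layer 69.7%
{'epithelial': 23.7, 'endothelial': 19.5, 'mesenchymal': 56.7}
```

The generator placed endothelial and mesenchymal nuclei with 68 % of each
class in the first cell layer; the full pipeline (segmentation → detection
→ classification → distance records) recovers 69.9 % and 69.7 % — within
2.5 percentage points of the realized truth (67.4 % / 68.9 % at this seed).
The composition line is the cell-type breakdown among all cells within
15 µm of the epithelial surface.

The same analyses run from the shell:

```bash
pancshell phantom generate --config spec.yaml --out phantom/   # OME-TIFF + truth CSVs
pancshell analyze 3d --config analysis.yaml --out results/     # tables, plots, provenance
pancshell analyze sections --config analysis.yaml              # 2D pipeline
pancshell report stats --config groups.yaml                    # MWU / KW + Dunn-Holm
```

`analyze 3d` writes `distance_records.csv`, `layer_fractions.csv`,
`composition.csv`, `vessel_segments.csv`, `diameter_histogram.csv`,
`vascular_volume_fraction.csv`, `cluster_microenvironment.csv`, cumulative
frequency and histogram plots, and a `provenance.json` (config hash, seed,
version). Reruns with the same config and seed are byte-identical.

## What this is not

No proprietary-format readers (`.ims`/`.wrl`), no remote data-repository
client, no registration/stitching, no
flow modeling, and no biological interpretation — the package measures; the
science of what the numbers mean stays with the user. See
`docs/methods.md` for the models, conventions and limitations.
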