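# embryoseg

Batch segmentation of **nuclei and cells in 3D fluorescence microscopy
volumes** — confocal stacks of early embryos, spheroids and similar
nuclei-based samples — with per-cell quantification of morphology and
protein expression, plus a simulated-embryo generator and ground-truth
metrics for benchmarking the whole pipeline.

It is aimed at labs that need reproducible, scriptable 3D analysis:  every
run is driven by a single flat parameter file, outputs are plain OME-TIFF
label volumes and CSV tables, and re-running with the same file and inputs
reproduces results bit-for-bit.

## The pipeline

The stage order is fixed:

1. **Detect nuclear centres** with one of two blob detectors on the nuclear
   channel: *basic* — scale-normalised Laplacian of Gaussian (fast, assumes
   roughly ellipsoidal nuclei) — or *advanced* — Hessian-eigenvalue
   blobness, `|λ1·λ2·λ3|^{1/3}` where all eigenvalues are negative, which
   finds bright blobs of any shape at extra cost.
2. **Suppress noise and background**: Gaussian smoothing, then a white
   top-hat with an ellipsoidal (anisotropy-aware) structuring element,
   optionally on a downsized copy for speed.
3. **Segment nuclei** by marker-controlled watershed: the anisotropic
   Euclidean distance transform of the detected-centre mask is flooded from
   the centres, restricted to a global-threshold mask (Otsu, triangle, …)
   of the background-subtracted nuclear channel.
4. **Segment cells** with the nuclei as seeds.  With a volumetric cell
   marker the flooded map is the EDT of the nuclei; with a membrane marker
   it is a geodesic distance in which a voxel step costs

   $$d(i,j)=\sqrt{\frac{\lambda\,\lVert x_i-x_j\rVert^2+(I_i-I_j)^2}{\lambda+1}}$$

   so bright membranes act as barriers; as λ→∞ this tends to the Euclidean
   distance.
5. **Measure and classify**: nuclear/cell volumes and their ratio,
   nuclear and cytoplasmic mean intensities per channel, nuclear/cytoplasmic
   ratios, normalised expression (e.g. to DAPI), and an inner/outer class
   per cell — *inner* iff $D_i < D_T\,D_m$, where $D_i$ is the distance of
   the nuclear centroid from the embryo centroid (mean of all nuclear
   centroids), $D_m$ the maximum such distance and $D_T$ a threshold
   (default 0.5).

Validation uses simulated embryos — non-overlapping random ellipsoidal
nuclei in a sphere, Voronoi-style cells and membranes, depth attenuation,
Gaussian PSF, sub-sampling, gamma noise — scored by the absolute cell-count
error $E_c=\lvert N_{gt}-N_{seg}\rvert$, nuclear/cell centroid localisation
errors ($E_{nl}$, $E_{cl}$, Hungarian-matched) and detection sensitivity.

## Worked example

Simulate a half-scale eight-cell embryo at SNR 10, then run the full
pipeline on it:

```bash
embryoseg simulate --n-cells 8 --snr 10 --seed 1 --output sim/
embryoseg detect --config examples/halfscale_params.yml \
    --input sim/embryo.ome.tif --output detections.csv
embryoseg evaluate --truth-centroids sim/truth_centroids.csv \
    --detections detections.csv --match-radius 5 --output matches.csv
embryoseg run --config examples/halfscale_params.yml \
    --input sim/embryo.ome.tif --output results/
```

(`examples/halfscale_params.yml` is the shipped parameter file matched to
the half-scale simulations; the same file is what `run` copies next to its
outputs for reproducibility.)

or equivalently in Python:

```python
from embryoseg import simulate_embryo, match_and_localise
from embryoseg.simulate import scaled_down_params
from embryoseg.evaluate import default_grid_config
from embryoseg.pipeline import process_volume

image, truth = simulate_embryo(scaled_down_params(n_cells=8, target_snr=10, seed=1))
result = process_volume(image, default_grid_config("advanced"))
print(result.n_cells)                       # all nuclei found and segmented
table = result.table()
print(table[["cell_id", "nucleus_volume_um3", "cell_volume_um3", "inner_outer"]])
```

prints, for the first cells,

```
8
   cell_id  nucleus_volume_um3  cell_volume_um3 inner_outer
0        1               53.00           389.36       outer
1        2               52.20           331.16       outer
2        3               49.32           284.20       outer
...
```

i.e. the count is exactly right and every segmented nucleus has a volume of
the order of the generated ellipsoid (4/3·π·2.5·1.875·1.875 ≈ 36.8 μm³ at
half scale; the segmentation is slightly dilated by the PSF and the global
threshold), cell bodies are several times larger, and cells are split into
inner/outer sub-populations by their distance from the embryo centroid —
an eight-cell embryo has no deep interior, so all cells here are outer.

The validation sweep (63 SNR × cell-count conditions × 3 replicates) is
available as:

```bash
embryoseg validate-grid --seed 1 --output grid/
```

which writes per-embryo metrics, pooled localisation errors, tile-mean
heat-map tables and a summary CSV.

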