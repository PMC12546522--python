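# aneuhemo

Post-processing toolkit for aneurysm hemodynamics and wall radiomics:

* **WSS wall metrics** — per-point TAWSS, OSI, ECAP and RRT from a
  time-resolved wall-shear-stress vector series on a triangulated sac
  surface, with area-weighted sac summaries (avg OSI / ECAP / RRT,
  mean / max TAWSS).
* **Vortex-core analysis** — per-cell velocity-gradient tensors on
  tetrahedral meshes (linear interpolation, exact for affine fields),
  Q-criterion or lambda2 core masks, vortex volume (VV), number of cores
  (NOC), NOC standard deviation over the cycle, and the degree of volume
  overlap (DVO, Jaccard) between adjacent cardiac phases.
* **Morphometry** — surface area, enclosed volume, sac height/width from a
  neck plane and inflow direction, aspect ratio, and size ratio.
* **Radiomics** — from-scratch first-order, GLCM, GLRLM, GLSZM, GLDM and
  NGTDM features (28 named features) on masked 3-D images, verified against
  independent brute-force enumerations.
* **Correlation screening** — Spearman rank correlations between radiomic
  features and morphology / WSS / vortex parameters, overall and per
  subgroup, with strong-pair flagging (|rho| > 0.7, p < 0.05 by default)
  and cohort screening-summary arithmetic.
* **Synthetic data** — generators with planted, analytically known ground
  truth (icospheres, tetrahedralized balls, pulsatile WSS series with known
  OSI, Gaussian-rotation vortex blobs, textured image volumes, Gaussian
  copula cohorts), so the whole pipeline is testable without patient data.

## CLI

```bash
aneuhemo simulate wss|vortex|image|cohort --config cfg.yaml --seed 1 --out dir/
aneuhemo wss        --in series_dir/ --weighting area --out out/
aneuhemo vortex     --in series_dir/ --criterion Q --threshold 0.036 --min-cells 32 --out out/
aneuhemo morphology --sac sac.stl --config case.yaml
aneuhemo radiomics  --image image_dir/ --out features.csv
aneuhemo correlate  --cohort cohort.csv --threshold 0.7 --mode abs --out out/
aneuhemo run        --config demo.yaml --out run_dir/
```

`aneuhemo run` executes the full synthetic demo (morphology → WSS → vortex
→ radiomics → correlation screen) and writes a cohort table, a correlation
table, a strong-pair report, and a manifest; reruns of the same config are
byte-identical.

Field series live in a directory with a `series.json` index, a `mesh.vtk`
(legacy ASCII VTK) and either per-phase VTK files or a long-format CSV.
Images and masks are NIfTI with a `rois.json` sidecar.

## Notes on vortex-core extraction

The Q > 0 rule on piecewise-linear gradients picks up interpolation noise
in regions of near-zero velocity.  Two documented guards handle this: a
small positive threshold (about 1e-3 of the expected core Q level) removes
far-field roundoff speckle, and the `min_cells` component filter removes
small fringe fragments that detach from the core under face adjacency.
Both are configurable and recorded in the output metadata.

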