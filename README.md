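# sparsebone

Sparse-view micro-CT reconstruction and quantitative trabecular bone
morphometry, evaluated on calibrated synthetic phantom cohorts.

## The problem

Micro-CT is the standard tool for quantifying subchondral bone structure in
small-animal models of osteoarthritis, but full short-scan acquisitions are
slow and deposit a radiation dose that matters for longitudinal and in-vivo
work.  Iterative reconstruction promises the same *morphometric* answers
from a fraction of the projection views.  `sparsebone` provides the whole
evaluation pipeline needed to test that promise quantitatively:

1. **synthetic phantoms** — three-material volumes (air, soft tissue, bone)
   with a subchondral plate over a layered plate-and-strut trabecular
   network, generated from seeded stationary Gaussian random fields and
   calibrated so that cohorts hit prescribed group statistics
   (BV/TV, Tb.Th, Pl.Th means ± SD for an operated "ACLT" group and an
   unoperated control group);
2. **forward model** — parallel-, fan- and small-cone-beam geometries, a
   Joseph ray-driven projector with an exact adjoint, Poisson photon noise
   with frame averaging, and angular subsampling (260 views at 0.7°
   reduced to 130 / 65 / 44);
3. **reconstruction** — Hamming-apodized FBP/FDK (α = 0.54, Parker-weighted
   short scan) as the full-data reference, plus three iterative methods on
   reduced data: CGLS, total-variation regularization minimized with
   Barzilai–Borwein steps (λ chosen by the L-curve corner), and DART, the
   discrete algebraic reconstruction technique with a three-value gray
   prior (CGLS as its algebraic inner solver);
4. **segmentation** — median + unsharp prefilter, global 3-D Otsu
   threshold, keep-largest despeckling, pore filling and morphological
   closing for the plate;
5. **morphometry** — direct-3D structural parameters: BV/TV, Tb.Th and
   Tb.S by largest-inscribed-sphere local thickness, Tb.N by the direct
   identity Tb.N = (BV/TV)/Tb.Th, the ellipsoid factor
   EF = a/b − b/c (maximal inscribed ellipsoids, a ≤ b ≤ c; rods → +1,
   plates → −1), and plate thickness Pl.Th;
6. **evaluation** — the full {FBP@full} ∪ {CGLS, TV, DART} × {1/2, 1/4,
   1/6} grid, group descriptives, exact tie-aware Mann–Whitney tests
   (one- and two-tailed), relative errors against the full-data reference,
   and contrast-to-noise ratios.

## Worked example

Reconstruct one synthetic control sample from a sixth of its views with
DART and measure its morphometry:

```python
from sparsebone import (CohortSpec, sample_cohort, StudyConfig, TomoOperator,
                        forward_project, add_noise, subsample_projections,
                        ReconConfig, GrayPrior, dart, segment, compute_all)

vol, gt = sample_cohort(CohortSpec.control(n=1, base_seed=1))[0]
geom = StudyConfig().geometry()               # 260 views, 0.7°, fan beam
sino = add_noise(forward_project(vol, geom), i0=5e4, frames_m=2, seed=1)
sparse = subsample_projections(sino, 6)       # 44 views
rec = dart(sparse, TomoOperator(sparse.geometry),
           GrayPrior(CohortSpec.control(1).gray_values), ReconConfig(seed=1))
trab, plate = segment(rec, gt.region_masks)
res = compute_all(trab, plate, gt.region_masks["trabecular"],
                  vol.voxel_size_um, ef_seed=1)
for k, v in res.as_dict().items():
    print(f"{k:12s} {v: .3f}")
```

prints

```
bvtv_pct      51.528
tbth_um       196.241
tbs_um        171.759
tbn_per_mm    2.626
ef           -0.537
plth_um       563.890
```

i.e. from 44 of 260 views DART recovers a bone volume fraction of 51.5 %
(the sample was drawn against control targets of 51.9 ± 3.4 %), a mean
trabecular thickness of 196 µm, a trabecular number of 2.63 mm⁻¹ derived
from the two, a strongly oblate (plate-like, EF < 0) architecture, and a
564 µm subchondral plate.

The full study — both cohorts, all four algorithms, every reduction level,
statistics and report files — is one call (or `sparsebone study --out dir`):

```python
from sparsebone import StudyConfig, run_study, report
result = run_study(StudyConfig(master_seed=0))
report(result, "results/")
```

A command-line interface mirrors each stage
(`sparsebone simulate | project | reduce | reconstruct | segment | morph |
study | report`); every run is deterministic under its `--seed` and study
outputs carry a manifest with config, seeds and content hashes.

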