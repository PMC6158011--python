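# axonmatch

Identify fluorescently labeled axons inside dense 3D electron-microscopy
reconstructions — no chemical label conversion, no artificial fiducials,
just trajectories.

## The problem

Correlative light/electron microscopy of nervous tissue gives you two views
of the same neuropil: a fluorescence (LM) volume in which a sparse set of
axons carries a label of known origin, and an EM volume in which every
neurite can be reconstructed but the label is invisible.  Intrinsic
fiducials (blood-vessel bifurcations) support only a coarse LM→EM
registration, with a precision λ_align of ~5–10 µm — dozens of axons fit
inside that error ball.  The way out is geometric: axons that share a small
seed volume diverge, and after a *uniqueness length* d_unique no other
seed-box axon remains within λ_align of a given trajectory.  If labeled
axons can be followed in LM for at least d_unique, their EM counterparts are
identified by elimination.

`axonmatch` implements that toolchain:

- **skeletons / io_formats** — tree skeletons in physical nm; webKnossos NML,
  SWC, control-point CSV, multi-page TIFF, JSON reports.
- **uniqueness** — the marching-sphere measurement: per-axon d_unique, the
  population fraction-unique curve and d_unique90
  (`d_unique90 = smallest distance at which ≥90% of axons are unique`),
  λ sweeps, and a bootstrap test comparing populations of unequal size.
- **registration** — Horn quaternion affine fits with anisotropic scale
  (`y = R·diag(s)·x + t`), multi-level cubic B-spline free-form deformation
  (32 µm initial knots, four bisecting refinements, ridge-damped), held-out
  residual reports and residual-vs-control-point-count bootstrap curves.
- **matching** — persistent-candidate ranking of EM axons along a
  transformed LM template, varicosity-seeded reduced search boxes, and an
  iterative match session that accumulates control points and refits the
  transform as it goes.
- **varicosity_stats** — equivalent sphere diameters d = 2·(3V/4π)^(1/3),
  LM ellipsoid volumes from Gaussian FWHM profile fits, a randomization test
  for varicosity-pattern matches, and prevalence-weighted KDE likelihoods of
  a varicosity being a synaptic bouton.
- **volume_overlap** — per-plane binarization/segmentation of LM stacks,
  matched-signal fraction, labeling density.
- **synthetic** — ground-truthed scene generator (persistent-random-walk
  axon populations, sparse deformed LM views, varicosities, control points)
  that makes every stage testable without any data download.

See `docs/methods.md` for the algorithms and their numerical conventions.

## Worked example

Generate a synthetic scene, fit the coarse affine from its blood-vessel-like
control points, and identify one LM axon in the dense EM population:

```python
import numpy as np
from axonmatch import (fit_affine, generate_scene, persistent_candidates,
                       path_length, uniqueness_lengths, UniquenessParams)

scene = generate_scene(seed=3)           # 220 EM axons, deformed LM view
aff = fit_affine(scene.control_points)   # coarse LM->EM registration

params = UniquenessParams.cubic(scene.config.volume_extent / 2, 5000.0)
curve = uniqueness_lengths(scene.em_skeletons, params)
unique = curve.d_unique[curve.d_unique >= 0]
print(f"{len(unique)}/{curve.n_axons} axons unique, "
      f"mean d_unique {unique.mean()/1000:.1f} um")

lm = max(scene.lm_skeletons, key=path_length)
ranking = persistent_candidates(lm.transformed(aff.apply),
                                scene.em_skeletons,
                                scene.config.seed_box, lambda_align=5000.0)
print("best EM candidate:", ranking.best.em_axon_id,
      "truth:", scene.correspondence[lm.tree_id])
```

Output:

```
98/220 axons unique, mean d_unique 65.7 um
best EM candidate: 126 truth: 126
```

The first line is the uniqueness analysis of the synthetic population (the
minimal trajectory model produces more near-parallel axon pairs than real
tissue — see `docs/methods.md`); the second shows the matching stage
recovering the correct ground-truth partner of the longest LM fragment.
Across all LM fragments of ≥40 µm on these scenes, recovery is 96–100%.

The same pipeline is available from the shell:

```bash
axonmatch simulate --seed 5 --out-dir scene/
axonmatch register --cps scene/control_points.csv --mode affine --out t.json
axonmatch uniqueness --nml scene/em.nml --lambda-um 5 \
    --box-center-um 65 55 42.5 --out curve.json
```

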