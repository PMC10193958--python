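# varimap

Multiscale varifold-measure representation and mapping of spatial
molecular and tissue data.

## The problem

Modern brain-mapping data lives at wildly different scales: single RNA
molecules and tau tangles at micrometers, typed cells, laminar tissue
bands, and MR images at millimeters. At the finest scales nothing is
smooth — the data are point clouds of discrete particles with functional
marks — while atlas-scale anatomy is treated as a smooth continuum.
`varimap` implements one representation that covers the whole range:
every dataset is a weighted, feature-marked measure

    mu = sum_i w_i delta_{x_i} (x) delta_{f_i},

a "varifold" measure on space x features, where the feature f_i may be a
particle size, a gene identity, a cell-type probability simplex, a spike
train, or an image intensity. On top of this single data structure the
package provides:

- **Renormalization across scales** — transition kernels that resample
  particle weight onto computational lattices (Gaussian cell integrals or
  nearest-cell assignment) and reduce the per-site conditional feature
  laws to summary features: moments of particle size, entropy,
  gray-level decision-region probabilities, peristimulus-time Fourier
  coefficients of spike trains, cell-type posteriors (PCA + Gaussian
  mixture), and tissue types from Fisher–Rao k-means on the simplex.
  Every scale of the resulting cascade is again a measure.
- **Varifold norms** — separable Gaussian kernels on space x features
  give a dual RKHS norm ||mu_a - mu_b||_{W*} that compares measures with
  different particle counts and no correspondences, at every scale, for
  every data modality.
- **Multiscale hierarchical LDDMM** — a hierarchy of diffeomorphisms,
  one per scale with successively refined controls u^l = u^{l-1} + v^l,
  flows all scales jointly. Geodesics are parameterized by initial
  spatial and weight momenta (p^x, p^w) and integrated with RK4 from the
  Hamiltonian equations; diffeomorphisms act on measures by "copy and
  paste" (weights multiply by |det dphi|, so expanding tissue gains
  mass). Registration minimizes path energy plus the multiscale varifold
  mismatch by geodesic shooting, with gradients from an exact discrete
  RK4 adjoint (or finite differences as a cross-check).
- **Synthetic scenes** — seeded generators for marked Poisson fields,
  layered cortical bands, MERFISH-like RNA/cell scenes, Poisson spike
  trains and ground-truth deformed pairs, which are also the test bed.

## Worked example

Renormalize a layered scene to tissue scale, then recover a known
deformation by multiscale matching:

```python
import numpy as np
from varimap import CumulativeKernel, Grid, VarifoldKernelSpec
from varimap.renormalize import Stage, cascade
from varimap.synthetic import gen_layered_band, gen_deformed_pair
from varimap.geodesics import match

# layered "cortex" scene: mean particle size rises with depth
mu = gen_layered_band((0, 0), (30, 30), layer_means=[10.0, 40.0, 80.0],
                      layer_sd=2.0, intensity=1.0, seed=7)
print(f"scene: {mu.n} particles, total mass {mu.weights.sum():.0f}")

stage = Stage(Grid((0, 0), (30.0, 3.0), (1, 10)), sigma=2.5, reduce="mean_var")
lat = cascade(mu, [stage])[0]          # coarsest scale of the cascade
print("tissue-scale mean size by depth:",
      np.array2string(lat.site_features.as_matrix()[:, 0], precision=1))

# registration recovery on a ground-truth deformed pair
base = gen_layered_band((0, 0), (10, 10), [1.0], 0.1, 0.4, seed=8)
kern = CumulativeKernel.from_fwhm([6.0])
tpl, tgt, truth = gen_deformed_pair(base, kern, momenta_scale=0.2, seed=9)
res = match(tpl, tgt, kern, [VarifoldKernelSpec(1.0, 1.0)],
            alpha=20.0, steps=15, max_iter=60)
print(f"mismatch: {res.mismatch_trace[0]:.3f} -> {res.mismatch_trace[-1]:.5f} "
      f"({res.mismatch_trace[-1]/res.mismatch_trace[0]:.2%} of initial)")
err = res.flow.states[-1].positions[0] - truth["flow"].states[-1].positions[0]
d = truth["flow"].states[-1].positions[0] - truth["flow"].states[0].positions[0]
print(f"position RMSE {np.sqrt((err**2).sum(1).mean()):.4f} "
      f"vs mean true displacement {np.linalg.norm(d, axis=1).mean():.3f}")
print(f"Hamiltonian drift {res.flow.hamiltonian_drift():.2e}")
```

Output:

```
scene: 911 particles, total mass 911
tissue-scale mean size by depth: [10.1 10.5 14.4 26.1 37.2 42.8 55.5 72.3 79.1 80.1]
mismatch: 34.813 -> 0.00669 (0.02% of initial)
position RMSE 0.0270 vs mean true displacement 1.198
Hamiltonian drift 2.61e-10
```

The depth profile reproduces the 10/40/80 um^2 layer means with smooth
transitions at the band boundaries (the cascade warns that this lattice
does not pad the support by 6 sigma — intended here, since the grid is
the observation window). The matcher drives the varifold mismatch to
0.02% of its initial value and recovers the flowed particle positions to
about 2% of the mean true displacement, while conserving the Hamiltonian
along the shot geodesic to 3e-10.

A command-line interface mirrors the library:

```sh
varimap simulate pair --seed 1 -o scene/
varimap match --template scene/template.json --target scene/target.json \
        --config cfg.toml -o out/
varimap norm --a a.csv --b b.csv --sigma-x 1.0 --sigma-f 1.0
```

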