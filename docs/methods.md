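# Methods

## Measures as the universal representation

Every dataset handled by `varimap` — detected histology particles, RNA
molecules, typed cells, spike-recorded neurons, raster images — is stored
as a weighted, feature-marked particle measure

    mu = sum_i w_i delta_{x_i} (x) delta_{f_i},

with positions in physical units, strictly positive weights, and a
homogeneous feature column (scalar, vector, probability simplex, complex
vector, or strictly increasing spike-time list). Dense images enter the
same framework as pixel-particle measures: one particle per voxel center,
weight equal to voxel volume, intensity as scalar feature. Coincident
particles are kept, not merged; `disintegrate` exposes the spatial
marginal and per-position conditional feature laws on demand, and the
round trip reproduces the measure up to particle order.

Diffeomorphisms act by "copy and paste": positions move through the map,
each weight picks up |det dphi| and features ride along unchanged.
Expanded tissue therefore gains mass — deliberately unlike mass-preserving
measure transport, because biological constituents replicate rather than
dilute. When no analytic Jacobian is supplied, central differences with
step 1e-4 times the domain diameter are used; the action tests compare
both routes.

## Crossing scales: the (T1, T2) cascade

A scale transition is a transition kernel applied to the measure. T1 is
linear spatial resampling onto a lattice of half-open cells: site weights
are `w_j = sum_i w_i pi(x_i, Y_j)` with `pi` either a Gaussian cell
integral (per-axis error functions; a partition of unity over a complete
tiling) or a nearest-cell indicator. Site conditional laws collect the
contributing particles with probabilities proportional to transferred
weight; empty sites carry weight zero and are excluded from norms and
clustering rather than imputed. Mass is conserved to round-off whenever
the lattice pads the support by six standard deviations (the escaping
tail is ~2e-9 of the mass); a narrower lattice triggers a warning rather
than an error, since boundary truncation is sometimes intended.

T2 reduces each site law to a feature vector:

- **moments** — mean and variance (or mean, mean-square, entropy) of
  scalar features such as particle size; entropy is Shannon entropy of
  the atom probabilities in natural log (the output metadata records the
  base), with 0 ln 0 = 0.
- **Bayes decision regions** — integrating a gray-level law over a
  partition of [0, 256) yields tissue-class probabilities.
- **PST Fourier** — spike trains are binned into a peristimulus-time
  histogram; the law-averaged per-bin fractions are Fourier transformed
  over the 1-based bin index with omega = 2 pi / B and harmonics
  n = 0..n_max <= B-1. The bin count B is a required parameter. The
  fundamental frequency of the transform is one cycle per histogram span,
  so phase-locking analyses should bin a single stimulus period (folding
  spike times modulo the period); phi_0 is then the covered-rate check
  and |phi_n| the vector strength.
- **cell typing** — RNA molecules join their nearest cell center, cells
  are weighted by RNA count, and a pluggable typer maps the per-cell gene
  composition matrix to type-probability simplices. The default typer is
  PCA to q = min(20, #genes, #cells-1) components followed by a
  full-covariance Gaussian mixture (10 EM restarts, fixed seed,
  covariance regularization 1e-6). Zero-RNA cells are flagged and
  dropped; how they should enter downstream laws is data-dependent and
  left to the caller.
- **tissue typing** — Fisher-Rao k-means on the cell-type simplices, then
  per site the law-weighted frequency of each tissue class.

The Fisher-Rao distance on the simplex uses the closed form
d = 2 arccos(sum_k sqrt(p_k q_k)). k-means runs in the square-root
embedding (the positive orthant of the unit sphere, where the metric is
twice the arc length): k-means++ seeding on embedded points, assignment
by maximal Bhattacharyya affinity (equivalent to minimal Fisher-Rao
distance), centroids as renormalized embedded means, best of several
seeded restarts. The iteration trace records the chordal objective, the
quantity Lloyd provably decreases; the reported objective is the
Fisher-Rao within-cluster sum of squares.

`cascade` chains (T1, T2) stages; the returned multiscale measure lists
scales coarse (l = 0) to fine, with the input as the finest scale.

## Varifold norms

Measures are compared in the dual of an RKHS on space x features with the
separable non-normalized Gaussian kernel k_W = exp(-|x-y|^2 / 2 sigma_x^2)
exp(-|f-g|^2 / 2 sigma_f^2); featureless mode sets the second factor to 1.
Simplex and one-hot features use the Euclidean distance inside the
Gaussian factor; complex spectral features use the complex modulus; spike
trains must be reduced (e.g. by PST Fourier) before entering a norm. The
squared norm of a difference is the exact three-block double sum — no
truncation or fast multipole, which keeps the implementation testable
against a literal double loop and is comfortable at the intended desk
scale of a few thousand particles per scale. Negative round-off down to
-1e-10 (relative) is clipped to zero; anything lower raises, since it
would indicate a real defect rather than cancellation noise.

The hierarchical norm is the plain sum of per-scale norms; optional
per-scale multipliers (default 1) let callers reweight scales. The
smoothed mismatch field h(y, f) = alpha K_W(mu - mu_obs) and its
closed-form spatial gradient give the endpoint momenta
p1x_i = -w_i grad_x h, p1w_i = -h, the exact negative gradients of the
endpoint cost — verified against finite differences.

For law-of-large-numbers experiments the distance between a weighted
empirical sample and its generating continuum law (uniform rectangle
times a finite atomic feature law) is computed with closed-form
error-function integrals for the cross and self terms, so the measured
n^{-1/2} convergence rate carries no quadrature error.

## Hierarchical geodesics

Each scale carries its own diffeomorphism; controls refine successively,
u^l = u^{l-1} + v^l, with v^l in the RKHS of a Gaussian Green's function
g_l specified by FWHM (FWHM = 2 sqrt(2 ln 2) sigma), listed coarse to
fine. The Gaussian choice is deliberate: the costate dynamics need kernel
derivatives to third order and the adjoint to fourth, all closed-form for
Gaussians. Matern/operator-induced kernels are a possible extension but
are not implemented.

The optimal control at scale l averages Green's functions across scales
through the cumulative kernel gbar_{min(l,j)} = sum_{m <= min(l,j)} g_m:

    u^l(.) = sum_j sum_i [ gbar_{l^j}(x_i^j, .) p_i^{x,j}
             + p_i^{w,j} w_i^j grad_1 gbar_{l^j}(x_i^j, .) ].

Geodesics are shot from initial momenta by classical RK4 on a uniform
grid over [0, 1] (default 20 steps for matching, 50+ for verification; no
adaptive stepping, for bit-reproducibility), with the control rebuilt
from (q, p) at every stage. Weights evolve multiplicatively
(w(t) = w(0) exp integral div u), hence stay positive along any finite
flow; a non-finite state aborts with the failing step index.

Two independent energy evaluations are kept deliberately distinct: the
costate pairing (1/2) p . xi_q(u) and the direct RKHS double sum of the
refinements v^l (kernel values, first and mixed-second derivatives
between source pairs). Their agreement to 1e-8 on random multi-scale
instances is a structural self-check of the control formula, not a
tautology. The Hamiltonian is conserved to < 1e-4 relative drift over
50 RK4 steps at moderate momenta.

`verify_momentum_integral` checks the boundary-anchored integral form of
the costates: forward Jacobians F_t of the flow are integrated with RK4
sharing the trajectory's stages, the time integral of transported
grad-div terms accumulates by the trapezoid rule, and the maximum
relative residual against the ODE costates is returned (second-order in
the step, ~1e-6 at 100 steps for typical instances, pure
transposed-Jacobian transport when the weight costates vanish). The
0-anchored block is implemented; the printed source of the 1-anchored
variant is typographically inconsistent, and the 0-anchored form is the
one consistent with the costate ODEs.

## Matching

`match` minimizes J(p0) = H(q0, p0) + (alpha/2) sum_l |mu^l(1) -
mu_obs^l|^2 over initial momenta with L-BFGS-B from a zero start. The
path-energy term is the initial Hamiltonian (conserved along exact
geodesics); diagnostics also report the trapezoid quadrature along the
flow to expose integration drift. Optimizing initial momenta rather than
full time-dependent controls is justified by the Pontryagin structure of
the problem and keeps the parameter count at (d+1) x N per scale; momenta
may be restricted to a subset of scales by zero-weighting.

Gradients come in two modalities. The default is a hand-derived discrete
adjoint of the RK4 integrator: exact vector-Jacobian products of the
Hamiltonian vector field (Gaussian derivative tensors through fourth
order, assembled per source/query scale block), pulled back through the
recomputed RK4 stages, plus the analytic dH/dp0 (H is a quadratic form in
the momenta). The alternative is central finite differences of the full
objective. The two agree to ~1e-9 relative on smoke instances; the test
suite enforces 1e-4. The adjoint costs about two shoots per gradient
regardless of particle count, which is what makes recovery experiments
with hundreds of momenta parameters affordable.

Diagnostics include objective/energy/mismatch traces (non-increasing over
accepted iterates), Hamiltonian drift, and the transversality residual
|p(1) + grad_{q1} U| normalized by the larger of the two momentum
magnitudes.

## Synthetic scenes and what they do (not) show

The generators are pure functions of (parameters, seed) and default to
desk scale: marked Poisson fields of ~10^2-10^3 particles, layered bands
with three layers of mean particle size (10, 40, 80) um^2 emulating a
laminar size gradient, MERFISH-like scenes with 50 cells / 9 genes / 3
types and Poisson(50) RNA per cell (`FULL_SCALE_RNA_PRESET` holds a
survey-scale 167-gene / 17-type demonstration configuration that the
tests do not exercise), inhomogeneous-Poisson spike trains by thinning
(simpler to verify
than time rescaling; the rate bound is explicit), and deformed pairs
produced by shooting known Gaussian momenta. Scene-size and parameter
choices are the package's stated study conditions and are fixed once.

The type-gene mixture interpolates between type-exclusive gene blocks and
the uniform law with a separation parameter s; s = 1 gives disjoint
supports (typing must be perfect), s ~ 0.5 a moderately hard problem.
The generators deliberately omit imaging noise, segmentation errors,
spatially correlated gene expression and realistic tau morphology:
passing tests show the algorithms are correct on their own model
assumptions, not that the pipeline is robust to real histology artifacts.

## Numerical choices and limitations

- Exact O(n^2) kernel sums; practical to ~5,000 particles per scale.
- RK4 with fixed uniform steps; energy drift, not step control, is the
  accuracy diagnostic.
- The matcher's finite-difference mode scales linearly in parameter
  count and is intended for cross-checks, not production runs.
- Continuum (non-atomic) tissue equations are realized only through
  pixel-particle discretization; there is no continuum quadrature API.
- Half-open lattice cells [a, b) make tilings unambiguous; positions are
  physical with an explicit unit label, and no implicit pixel/um
  conversion is ever applied.
- All randomness flows through one seeded `numpy` generator per call; no
  global state.
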