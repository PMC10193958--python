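"""Crossing scales: T1 space resampling and T2 feature reduction.

A scale transition is a transition kernel acting on the measure: first a
linear spatial resampling (T1) that reapportions particle weight onto the
cells of a computational lattice,

    w_j = sum_i w_i pi(x_i, Y_j),
    nu_j = sum_i (w_i pi(x_i, Y_j) / w_j) delta_{f_i},

then a nonlinear feature reduction (T2) collapsing each site's conditional
feature law nu_j to a summary feature phi(nu_j): moments of particle size,
entropy, Bayes decision-region probabilities, peristimulus-time Fourier
coefficients, cell-type posteriors, or tissue-type frequencies from
Fisher-Rao k-means. Iterating (T1, T2) stages yields the multiscale
sequence of measures, every scale again a varifold measure.
"""

from __future__ import annotations

import dataclasses
import warnings
from collections.abc import Callable

import numpy as np
from scipy.special import erf

from .measures import (
    ConditionalLaw,
    Features,
    Grid,
    LatticeMeasure,
    MultiscaleMeasure,
    ParticleMeasure,
)
__all__ = [
    "resample_to_lattice",
    "moment_features",
    "bayes_reduce",
    "pst_fourier",
    "GaussianMixtureTyper",
    "rna_to_cells",
    "fisher_rao_distance",
    "kmeans_fisher_rao",
    "cells_to_tissue",
    "Stage",
    "cascade",
]


def _axis_weights(x: np.ndarray, edges: np.ndarray, sigma: float) -> np.ndarray:
    """(n, n_cells) Gaussian integrals of each particle over the 1-d cells."""
    s = sigma * np.sqrt(2.0)
    cdf = 0.5 * (1.0 + erf((edges[None, :] - x[:, None]) / s))
    return np.diff(cdf, axis=1)


def resample_to_lattice(
    mu: ParticleMeasure,
    grid: Grid,
    sigma: float | None = None,
    mode: str = "gaussian",
    keep_laws: bool = True,
) -> LatticeMeasure:
    """T1: reapportion particle weight onto lattice cells.

    ``mode="gaussian"`` uses the Gaussian transition weight
    pi_sigma(x, Y_j) (separable error-function integrals, partition of
    unity over a complete tiling); ``mode="nearest"`` assigns all weight to
    the cell containing the particle. Empty sites carry weight 0 and a
    None law. Total mass is conserved whenever the grid pads the particle
    support by at least 6 sigma (a warning is issued otherwise).
    """
    if mode not in ("gaussian", "nearest"):
        raise ValueError("mode must be 'gaussian' or 'nearest'")
    if mode == "gaussian":
        if sigma is None or not sigma > 0:
            raise ValueError("gaussian mode requires sigma > 0")
    if mu.dim != grid.dim:
        raise ValueError("grid and measure dimensions differ")
    n_sites = grid.n_sites
    if mu.n == 0:
        return LatticeMeasure(grid, np.zeros(n_sites), [None] * n_sites, unit=mu.unit)

    lo, hi = grid.extent()
    pad = 6.0 * sigma if mode == "gaussian" else 0.0
    pmin, pmax = mu.positions.min(axis=0), mu.positions.max(axis=0)
    if np.any(pmin - lo < pad - 1e-12) or np.any(hi - pmax < pad - 1e-12):
        warnings.warn(
            "lattice does not pad the particle support by 6 sigma; "
            "resampling will not conserve total mass",
            stacklevel=2,
        )

    if mode == "gaussian":
        per_axis = [
            _axis_weights(mu.positions[:, a], grid.edges(a), sigma)
            for a in range(grid.dim)
        ]
        if grid.dim == 1:
            P = per_axis[0]
        elif grid.dim == 2:
            P = np.einsum("ia,ib->iab", *per_axis).reshape(mu.n, n_sites)
        else:
            P = np.einsum("ia,ib,ic->iabc", *per_axis).reshape(mu.n, n_sites)
    else:
        P = np.zeros((mu.n, n_sites))
        idx_axes = []
        for a in range(grid.dim):
            ia = np.floor((mu.positions[:, a] - grid.origin[a]) / grid.spacing[a]).astype(int)
            idx_axes.append(np.clip(ia, 0, grid.counts[a] - 1))
        flat = np.ravel_multi_index(tuple(idx_axes), grid.counts)
        P[np.arange(mu.n), flat] = 1.0

    site_w = mu.weights @ P
    laws: list | None = None
    if keep_laws:
        laws = []
        for j in range(n_sites):
            if site_w[j] <= 0.0:
                laws.append(None)
                continue
            contrib = mu.weights * P[:, j]
            keep = contrib > 0.0
            idx = np.flatnonzero(keep)
            laws.append(
                ConditionalLaw(mu.features.take(idx), contrib[idx] / site_w[j])
            )
    return LatticeMeasure(grid, site_w, laws, unit=mu.unit)


def moment_features(nu: ConditionalLaw, which: str = "mean_var") -> np.ndarray:
    """T2 moment reduction of a conditional feature law.

    ``"mean_var"``: (mean, variance) of scalar features (elementwise for
    vectors). ``"mean_meansq_entropy"``: (mean, mean square, entropy), the
    tissue-scale summary used for cell-type laws; entropy is the Shannon
    entropy of the atom probabilities in nats, with 0 ln 0 = 0.
    """
    if len(nu.probs) == 0:
        raise ValueError("empty law")
    f = nu.atoms.as_matrix().real
    p = nu.probs
    m1 = p @ f
    m2 = p @ (f * f)
    if which == "mean_var":
        return np.concatenate([m1, np.maximum(m2 - m1 * m1, 0.0)])
    if which == "mean_meansq_entropy":
        return np.concatenate([m1, m2, [entropy(p)]])
    raise ValueError(f"unknown moment reduction {which!r}")


def entropy(probs: np.ndarray) -> float:
    """Shannon entropy in nats; zero-probability atoms contribute 0."""
    p = np.asarray(probs, dtype=float)
    nz = p > 0
    return float(-np.sum(p[nz] * np.log(p[nz])))


def bayes_reduce(nu: ConditionalLaw, regions) -> np.ndarray:
    """T2 Bayes reduction of a gray-level law to tissue-class probabilities.

    ``regions`` is a partition theta_1..theta_N of the gray range [0, 255]
    given as (lo, hi) pairs covering [0, 256) half-open; output p_n =
    nu(theta_n) sums to 1.
    """
    regions = [(float(a), float(b)) for a, b in regions]
    order = sorted(regions)
    lo0 = order[0][0]
    hi_prev = lo0
    for a, b in order:
        if b <= a or abs(a - hi_prev) > 1e-9:
            raise ValueError("regions must be disjoint and contiguous")
        hi_prev = b
    if abs(lo0 - 0.0) > 1e-9 or abs(hi_prev - 256.0) > 1e-9:
        raise ValueError("regions must cover the gray range [0, 256)")
    vals = nu.atoms.as_matrix().real.ravel()
    out = np.zeros(len(regions))
    for n, (a, b) in enumerate(regions):
        out[n] = nu.probs[(vals >= a) & (vals < b)].sum()
    if abs(out.sum() - 1.0) > 1e-9:
        raise ValueError("gray levels fall outside the stated regions")
    return out


def pst_fourier(nu: ConditionalLaw, bins: np.ndarray, n_max: int) -> np.ndarray:
    """Peristimulus-time Fourier features of a law over spike trains.

    Each train contributes its fraction of spikes per bin; the law-averaged
    fractions cbar_i are Fourier transformed over the (1-based) bin index
    with omega = 2 pi / B:

        phi_n = sum_{i=1..B} exp(j omega n i) cbar_i,  n = 0..n_max.

    phi_0 is the integrated rate (1 when the bins cover every spike);
    higher harmonics measure synchrony / phase locking.
    """
    bins = np.asarray(bins, dtype=float)
    if bins.ndim != 1 or len(bins) < 2 or not np.all(np.diff(bins) > 0):
        raise ValueError("bins must be an increasing edge vector")
    if nu.atoms.kind != "spike-times":
        raise TypeError("pst_fourier expects spike-time features")
    B = len(bins) - 1
    if not (0 <= n_max <= B - 1):
        raise ValueError("n_max must satisfy 0 <= n_max <= B-1")
    cbar = np.zeros(B)
    for train, p in zip(nu.atoms.data, nu.probs):
        if len(train) == 0:
            continue
        if np.any(train < bins[0]) or np.any(train >= bins[-1]):
            bad = train[(train < bins[0]) | (train >= bins[-1])][0]
            raise ValueError(f"spike at t={bad} falls outside the bin range")
        counts, _ = np.histogram(train, bins=bins)
        cbar += p * counts / len(train)
    n = np.arange(n_max + 1)
    i = np.arange(1, B + 1)
    phase = np.exp(1j * (2.0 * np.pi / B) * np.outer(n, i))
    return phase @ cbar


class GaussianMixtureTyper:
    """Default cell typer: PCA followed by a Gaussian-mixture posterior.

    Fits on the matrix of per-cell RNA compositions (rows sum to 1) and
    returns the posterior type-probability simplex per cell. The number of
    principal components defaults to min(20, n_genes, n_cells - 1).
    """

    def __init__(self, n_types: int, n_components: int | None = None,
                 seed: int = 0, n_init: int = 10, covariance_type: str = "full"):
        if n_types < 1:
            raise ValueError("n_types must be >= 1")
        self.n_types = n_types
        self.n_components = n_components
        self.seed = seed
        self.n_init = n_init
        self.covariance_type = covariance_type

    def fit_predict_proba(self, compositions: np.ndarray) -> np.ndarray:
        from sklearn.decomposition import PCA
        from sklearn.mixture import GaussianMixture

        X = np.asarray(compositions, dtype=float)
        n, g = X.shape
        if self.n_types == 1:
            return np.ones((n, 1))
        q = self.n_components or min(20, g, n - 1)
        q = max(1, min(q, g, n - 1))
        Z = PCA(n_components=q, random_state=self.seed).fit_transform(X)
        gm = GaussianMixture(
            n_components=self.n_types,
            covariance_type=self.covariance_type,
            n_init=self.n_init,
            random_state=self.seed,
            reg_covar=1e-6,
        ).fit(Z)
        return gm.predict_proba(Z)


def rna_to_cells(
    mu_rna: ParticleMeasure,
    cell_centers: np.ndarray,
    typer: GaussianMixtureTyper | Callable[[np.ndarray], np.ndarray] | None = None,
    n_types: int | None = None,
    seed: int = 0,
):
    """Aggregate RNA particles to cell centers and type the cells.

    Each RNA molecule (gene one-hot or count feature) joins its nearest
    cell center; the cell weight is its RNA count and its composition is
    the weight-averaged gene mixture. The pluggable ``typer`` maps the
    (n_cells, n_genes) composition matrix to type-probability simplices
    (default: PCA + Gaussian-mixture posterior). Returns
    (cell measure, info) where ``info`` carries the RNA->cell assignment,
    per-cell compositions, and indices of zero-RNA cells (flagged and
    dropped from the measure).
    """
    centers = np.atleast_2d(np.asarray(cell_centers, dtype=float))
    if centers.shape[0] < 1:
        raise ValueError("at least one cell center required")
    if typer is None:
        if n_types is None:
            raise ValueError("provide a typer or n_types")
        typer = GaussianMixtureTyper(n_types, seed=seed)

    d2 = (
        np.sum(mu_rna.positions**2, axis=1)[:, None]
        + np.sum(centers**2, axis=1)[None, :]
        - 2.0 * mu_rna.positions @ centers.T
    )
    assign = np.argmin(d2, axis=1)

    genes = mu_rna.features.as_matrix().real
    n_cells = centers.shape[0]
    counts = np.zeros(n_cells)
    comp = np.zeros((n_cells, genes.shape[1]))
    np.add.at(counts, assign, mu_rna.weights)
    np.add.at(comp, assign, mu_rna.weights[:, None] * genes)
    nonempty = counts > 0
    comp[nonempty] /= counts[nonempty, None]

    probs_fn = typer.fit_predict_proba if hasattr(typer, "fit_predict_proba") else typer
    simplices = np.asarray(probs_fn(comp[nonempty]), dtype=float)
    simplices = np.clip(simplices, 0.0, None)
    simplices /= simplices.sum(axis=1, keepdims=True)

    mu_cells = ParticleMeasure(
        centers[nonempty],
        counts[nonempty],
        Features("simplex", simplices),
        mu_rna.unit,
    )
    info = {
        "assignment": assign,
        "compositions": comp,
        "empty_cells": np.flatnonzero(~nonempty),
        "cell_index": np.flatnonzero(nonempty),
    }
    return mu_cells, info


def fisher_rao_distance(p, q) -> float:
    """Fisher-Rao geodesic distance between probability simplices,
    d(p, q) = 2 arccos(sum_k sqrt(p_k q_k)), in [0, pi] for laws (the
    Bhattacharyya affinity is nonnegative)."""
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.shape != q.shape:
        raise ValueError("simplices have different lengths")
    aff = float(np.sqrt(np.maximum(p, 0.0) * np.maximum(q, 0.0)).sum())
    return float(2.0 * np.arccos(np.clip(aff, 0.0, 1.0)))


def _fr_objective(S: np.ndarray, centroids_s: np.ndarray, labels: np.ndarray) -> float:
    aff = np.clip(np.einsum("nk,nk->n", S, centroids_s[labels]), 0.0, 1.0)
    return float(np.sum((2.0 * np.arccos(aff)) ** 2))


def kmeans_fisher_rao(laws, k: int, seed: int = 0, restarts: int = 5,
                      max_iter: int = 100, trace: list | None = None):
    """Lloyd k-means on the probability simplex under the Fisher-Rao metric.

    Works in the square-root embedding p -> sqrt(p) (the positive orthant
    of the unit sphere, where Fisher-Rao is twice the arc length): k-means++
    initialization on the embedded points, assignment by Fisher-Rao
    distance, centroids as renormalized means of the embedded members,
    squared back to the simplex. Best of ``restarts`` seeded runs; the
    within-cluster objective sum of d_FR^2 is non-increasing over Lloyd
    iterations (appended to ``trace`` when a list is passed). Returns
    (labels, centroids, objective).
    """
    P = np.atleast_2d(np.asarray(laws, dtype=float))
    n = P.shape[0]
    if not 1 <= k <= n:
        raise ValueError("k must satisfy 1 <= k <= number of laws")
    if np.unique(P, axis=0).shape[0] < k:
        raise ValueError("k exceeds the number of distinct laws")
    S = np.sqrt(np.clip(P, 0.0, None))
    rng = np.random.default_rng(seed)

    best = None
    for _ in range(max(1, restarts)):
        # k-means++ seeding in the embedding
        cent = np.empty((k, S.shape[1]))
        cent[0] = S[rng.integers(n)]
        d2 = np.sum((S - cent[0]) ** 2, axis=1)
        for c in range(1, k):
            tot = d2.sum()
            probs = d2 / tot if tot > 0 else np.full(n, 1.0 / n)
            cent[c] = S[rng.choice(n, p=probs)]
            d2 = np.minimum(d2, np.sum((S - cent[c]) ** 2, axis=1))
        labels = np.zeros(n, dtype=int)
        for _it in range(max_iter):
            aff = np.clip(S @ cent.T, 0.0, 1.0)
            new_labels = np.argmax(aff, axis=1)  # max affinity = min FR distance
            new_cent = cent.copy()
            for c in range(k):
                members = S[new_labels == c]
                if len(members):
                    m = members.mean(axis=0)
                    new_cent[c] = m / np.linalg.norm(m)
            if trace is not None:
                # embedded (chordal) objective: the quantity Lloyd provably
                # decreases; monotone per-term in the Fisher-Rao distance
                chord = S - new_cent[new_labels]
                trace.append(float(np.sum(chord * chord)))
            if np.array_equal(new_labels, labels) and np.allclose(new_cent, cent):
                break
            labels, cent = new_labels, new_cent
        obj = _fr_objective(S, cent, labels)
        if best is None or obj < best[2]:
            best = (labels.copy(), cent.copy() ** 2, obj)
    return best


def cells_to_tissue(
    mu_cells: ParticleMeasure,
    grid: Grid,
    sigma: float,
    k: int,
    seed: int = 0,
    restarts: int = 5,
) -> LatticeMeasure:
    """Aggregate typed cells to tissue-type probabilities on a lattice.

    Gaussian T1 resampling of the cell measure onto the grid, Fisher-Rao
    k-means of the cell-type simplices into k tissue classes, then per
    site the tissue feature is the law-weighted frequency of each tissue
    class under the site's conditional law.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    lat = resample_to_lattice(mu_cells, grid, sigma=sigma)
    cell_simplices = mu_cells.features.as_matrix().real
    labels, centroids, _ = kmeans_fisher_rao(cell_simplices, k, seed=seed, restarts=restarts)

    feats = np.zeros((grid.n_sites, k))
    # map each law atom (a cell simplex) to its k-means class
    lut = {}
    for s_row, lab in zip(cell_simplices, labels):
        lut[s_row.tobytes()] = lab
    for j, law in enumerate(lat.site_laws):
        if law is None:
            continue
        atom_mat = law.atoms.as_matrix().real
        for row, p in zip(atom_mat, law.probs):
            feats[j, lut[row.tobytes()]] += p
    return LatticeMeasure(
        lat.grid, lat.site_weights, lat.site_laws,
        Features("vector", feats), unit=mu_cells.unit,
    )


@dataclasses.dataclass
class Stage:
    """One (T1, T2) transition of the renormalization cascade.

    ``reduce`` maps a site ConditionalLaw to a reduced feature vector; the
    named shortcuts "mean_var" and "mean_meansq_entropy" use
    :func:`moment_features`.
    """

    grid: Grid
    sigma: float | None = None
    mode: str = "gaussian"
    reduce: str | Callable[[ConditionalLaw], np.ndarray] = "mean_var"

    def reducer(self) -> Callable[[ConditionalLaw], np.ndarray]:
        if callable(self.reduce):
            return self.reduce
        which = self.reduce
        return lambda law: moment_features(law, which)


def cascade(mu_fine: ParticleMeasure, recipe: list[Stage]) -> MultiscaleMeasure:
    """Run the scale cascade; scales are returned coarse to fine with the
    input measure as the finest scale.

    Each stage resamples the current (finer) measure onto its lattice and
    reduces the site laws to feature vectors; the reduced lattice, read as
    a particle measure at the nonempty sites, feeds the next stage.
    """
    scales = [mu_fine]
    current = mu_fine
    for s, stage in enumerate(recipe):
        lat = resample_to_lattice(current, stage.grid, stage.sigma, stage.mode)
        red = stage.reducer()
        feats = None
        rows = []
        for law in lat.site_laws:
            if law is None:
                rows.append(None)
                continue
            try:
                rows.append(np.atleast_1d(np.asarray(red(law), dtype=float)))
            except (TypeError, ValueError) as exc:
                raise TypeError(
                    f"stage {s}: feature reduction incompatible with feature kind "
                    f"{law.atoms.kind!r}: {exc}"
                ) from exc
        width = next((len(r) for r in rows if r is not None), 1)
        mat = np.zeros((lat.grid.n_sites, width))
        for j, r in enumerate(rows):
            if r is not None:
                mat[j] = r
        feats = Features("vector", mat)
        lat = LatticeMeasure(lat.grid, lat.site_weights, lat.site_laws, feats, lat.unit)
        scales.append(lat)
        current = lat.to_particles()
    return MultiscaleMeasure(scales[::-1])
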