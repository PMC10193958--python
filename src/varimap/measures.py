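"""Weighted, feature-marked particle measures.

The universal data structure at every spatial scale is a positive measure on
the product of physical space and a feature set,

    mu = sum_i w_i  delta_{x_i} (x) delta_{f_i},

with ``x_i`` a point in R^d (physical units, e.g. micrometers), ``w_i > 0``
a weight (a count, an area, a voxel volume, ...) and ``f_i`` a functional
feature: a scalar (particle size, image intensity), a vector, a probability
simplex (cell-type law), a complex vector (phase-locked spectral features)
or a strictly increasing list of spike times.

This module provides the measure containers, their disintegration into a
spatial marginal and conditional feature laws, the "copy and paste"
diffeomorphic action (positions move, weights pick up the Jacobian
determinant, features ride along unchanged), conversion of raster images to
pixel-particle measures, and i.i.d. sampling from a continuum law.
"""

from __future__ import annotations

import dataclasses
from collections.abc import Callable, Sequence
from typing import Union

import numpy as np

__all__ = [
    "FeatureValue",
    "Features",
    "ConditionalLaw",
    "ParticleMeasure",
    "Grid",
    "LatticeMeasure",
    "MultiscaleMeasure",
    "total_mass",
    "disintegrate",
    "reassemble",
    "apply_action",
    "image_to_measure",
    "sample_from_law",
    "UniformRectangle",
    "GaussianMixtureDensity",
]

FEATURE_KINDS = ("scalar", "vector", "simplex", "complex-vector", "spike-times", "none")

_SIMPLEX_TOL = 1e-9


def _check_simplex(v: np.ndarray) -> None:
    if np.any(v < -_SIMPLEX_TOL):
        raise ValueError("simplex feature has negative entries")
    if abs(float(v.sum()) - 1.0) > _SIMPLEX_TOL:
        raise ValueError(f"simplex feature sums to {float(v.sum())!r}, not 1")


@dataclasses.dataclass(frozen=True)
class FeatureValue:
    """A single functional feature: ``kind`` plus its numeric value.

    ``value`` is a scalar-like array for numeric kinds and a strictly
    increasing 1-d array of times (seconds) for kind ``"spike-times"``.
    """

    kind: str
    value: np.ndarray

    def __post_init__(self):
        if self.kind not in FEATURE_KINDS:
            raise ValueError(f"unknown feature kind {self.kind!r}")
        v = np.asarray(self.value)
        if self.kind == "complex-vector":
            v = v.astype(complex)
        elif self.kind != "none":
            v = v.astype(float)
        if not np.all(np.isfinite(v.view(float) if v.dtype == complex else v)):
            raise ValueError("feature value has non-finite entries")
        if self.kind == "simplex":
            _check_simplex(v)
        if self.kind == "spike-times":
            v = np.atleast_1d(v)
            if v.ndim != 1 or (len(v) > 1 and not np.all(np.diff(v) > 0)):
                raise ValueError("spike times must be strictly increasing")
        object.__setattr__(self, "value", v)

    def __eq__(self, other):
        return (
            isinstance(other, FeatureValue)
            and self.kind == other.kind
            and self.value.shape == other.value.shape
            and bool(np.array_equal(self.value, other.value))
        )

    def __hash__(self):
        return hash((self.kind, self.value.tobytes()))


class Features:
    """A homogeneous column of features attached to the particles.

    Numeric kinds are stored as an ``(n, k)`` array; spike trains as a list
    of 1-d arrays of unequal length. ``kind == "none"`` marks featureless
    particles (e.g. tau tangle detections carrying position only).
    """

    def __init__(self, kind: str, data):
        if kind not in FEATURE_KINDS:
            raise ValueError(f"unknown feature kind {kind!r}")
        self.kind = kind
        if kind == "spike-times":
            self.data = [np.atleast_1d(np.asarray(t, dtype=float)) for t in data]
            for t in self.data:
                if len(t) > 1 and not np.all(np.diff(t) > 0):
                    raise ValueError("spike times must be strictly increasing")
                if not np.all(np.isfinite(t)):
                    raise ValueError("non-finite spike time")
        elif kind == "none":
            self.data = np.zeros((int(data), 0))
        else:
            dtype = complex if kind == "complex-vector" else float
            arr = np.asarray(data, dtype=dtype)
            if arr.ndim == 1:
                arr = arr[:, None]
            if arr.ndim != 2:
                raise ValueError("numeric features must be an (n, k) array")
            flat = arr.view(float) if arr.dtype == complex else arr
            if not np.all(np.isfinite(flat)):
                raise ValueError("non-finite feature entries")
            if kind == "simplex":
                for row in arr:
                    _check_simplex(row.real)
            self.data = arr

    @classmethod
    def none(cls, n: int) -> "Features":
        return cls("none", n)

    def __len__(self):
        return len(self.data)

    def __getitem__(self, i: int) -> FeatureValue:
        if self.kind == "none":
            return FeatureValue("none", np.zeros(0))
        return FeatureValue(self.kind, self.data[i])

    def take(self, idx) -> "Features":
        if self.kind == "spike-times":
            return Features(self.kind, [self.data[i] for i in np.atleast_1d(idx)])
        if self.kind == "none":
            return Features.none(len(np.atleast_1d(np.arange(len(self))[idx])))
        return Features(self.kind, self.data[np.atleast_1d(idx)])

    def as_matrix(self) -> np.ndarray:
        """Numeric (n, k) view; spike trains must be reduced first."""
        if self.kind == "spike-times":
            raise TypeError("spike-time features have no fixed-width numeric form; "
                            "reduce them (e.g. renormalize.pst_fourier) first")
        return self.data

    def __eq__(self, other):
        if not isinstance(other, Features) or self.kind != other.kind:
            return False
        if self.kind == "spike-times":
            return len(self.data) == len(other.data) and all(
                np.array_equal(a, b) for a, b in zip(self.data, other.data)
            )
        return bool(np.array_equal(self.data, other.data))

    def __repr__(self):
        return f"Features(kind={self.kind!r}, n={len(self)})"


@dataclasses.dataclass
class ConditionalLaw:
    """Discrete probability law on features: atoms with probabilities."""

    atoms: Features
    probs: np.ndarray

    def __post_init__(self):
        self.probs = np.asarray(self.probs, dtype=float)
        if len(self.atoms) != len(self.probs) or len(self.probs) < 1:
            raise ValueError("atoms and probs must have equal positive length")
        if np.any(self.probs < -_SIMPLEX_TOL):
            raise ValueError("negative probability")
        if abs(float(self.probs.sum()) - 1.0) > _SIMPLEX_TOL:
            raise ValueError(f"probabilities sum to {float(self.probs.sum())!r}, not 1")


@dataclasses.dataclass
class ParticleMeasure:
    """Discrete measure ``sum_i w_i delta_{x_i} (x) delta_{f_i}``."""

    positions: np.ndarray  # (n, d), physical units
    weights: np.ndarray  # (n,), > 0
    features: Features | None = None
    unit: str = "um"

    def __post_init__(self):
        self.positions = np.atleast_2d(np.asarray(self.positions, dtype=float))
        self.weights = np.asarray(self.weights, dtype=float)
        n, d = self.positions.shape
        if d not in (1, 2, 3):
            raise ValueError(f"spatial dimension must be 1, 2 or 3, got {d}")
        if self.weights.shape != (n,):
            raise ValueError("positions and weights have mismatched lengths")
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("non-finite particle position")
        if n and not np.all(self.weights > 0):
            raise ValueError("weights must be strictly positive")
        if self.features is None:
            self.features = Features.none(n)
        if len(self.features) != n:
            raise ValueError("features length does not match particle count")

    @property
    def n(self) -> int:
        return len(self.weights)

    @property
    def dim(self) -> int:
        return self.positions.shape[1]

    def take(self, idx) -> "ParticleMeasure":
        idx = np.atleast_1d(idx)
        return ParticleMeasure(
            self.positions[idx], self.weights[idx], self.features.take(idx), self.unit
        )

    @classmethod
    def empty(cls, dim: int, kind: str = "none", unit: str = "um") -> "ParticleMeasure":
        feats = Features(kind, np.zeros((0, 1))) if kind not in ("none", "spike-times") \
            else (Features("spike-times", []) if kind == "spike-times" else Features.none(0))
        return cls(np.zeros((0, dim)), np.zeros(0), feats, unit)


@dataclasses.dataclass(frozen=True)
class Grid:
    """Regular lattice of half-open axis-aligned cells ``[a, b)``."""

    origin: tuple
    spacing: tuple
    counts: tuple

    def __post_init__(self):
        o = tuple(float(v) for v in np.atleast_1d(self.origin))
        s = tuple(float(v) for v in np.atleast_1d(self.spacing))
        c = tuple(int(v) for v in np.atleast_1d(self.counts))
        if not len(o) == len(s) == len(c):
            raise ValueError("origin/spacing/counts dimension mismatch")
        if any(v <= 0 for v in s) or any(v < 1 for v in c):
            raise ValueError("spacing must be > 0 and counts >= 1")
        object.__setattr__(self, "origin", o)
        object.__setattr__(self, "spacing", s)
        object.__setattr__(self, "counts", c)

    @property
    def dim(self) -> int:
        return len(self.origin)

    @property
    def n_sites(self) -> int:
        return int(np.prod(self.counts))

    def edges(self, axis: int) -> np.ndarray:
        return self.origin[axis] + self.spacing[axis] * np.arange(self.counts[axis] + 1)

    def centers(self) -> np.ndarray:
        """Cell centers, C-order raveled, shape (n_sites, d)."""
        axes = [
            self.origin[a] + self.spacing[a] * (np.arange(self.counts[a]) + 0.5)
            for a in range(self.dim)
        ]
        mesh = np.meshgrid(*axes, indexing="ij")
        return np.stack([m.ravel() for m in mesh], axis=-1)

    def extent(self) -> tuple[np.ndarray, np.ndarray]:
        lo = np.array(self.origin)
        hi = lo + np.array(self.spacing) * np.array(self.counts)
        return lo, hi


@dataclasses.dataclass
class LatticeMeasure:
    """Measure supported on a regular grid with per-site conditional laws.

    ``site_laws[j]`` is the conditional feature law at the j-th cell center
    (None marks an empty site, weight 0); ``site_features`` optionally holds
    reduced feature vectors after a feature-reduction step.
    """

    grid: Grid
    site_weights: np.ndarray
    site_laws: list | None = None
    site_features: Features | None = None
    unit: str = "um"

    def __post_init__(self):
        self.site_weights = np.asarray(self.site_weights, dtype=float)
        if self.site_weights.shape != (self.grid.n_sites,):
            raise ValueError("site_weights length must equal grid.n_sites")
        if np.any(self.site_weights < 0):
            raise ValueError("site weights must be nonnegative")
        if self.site_laws is not None and len(self.site_laws) != self.grid.n_sites:
            raise ValueError("site_laws length must equal grid.n_sites")
        if self.site_features is not None and len(self.site_features) != self.grid.n_sites:
            raise ValueError("site_features length must equal grid.n_sites")

    @property
    def dim(self) -> int:
        return self.grid.dim

    def to_particles(self) -> ParticleMeasure:
        """Nonempty sites as a particle measure (requires reduced features)."""
        keep = self.site_weights > 0
        centers = self.grid.centers()[keep]
        w = self.site_weights[keep]
        feats = None
        if self.site_features is not None:
            feats = self.site_features.take(np.flatnonzero(keep))
        if len(w) == 0:
            return ParticleMeasure.empty(self.dim, unit=self.unit)
        return ParticleMeasure(centers, w, feats, self.unit)


@dataclasses.dataclass
class MultiscaleMeasure:
    """Ordered sequence of measures, one per scale, coarse (l=0) to fine."""

    scales: list  # ParticleMeasure | LatticeMeasure
    descriptors: list | None = None  # free-form per-scale feature descriptor

    def __post_init__(self):
        if len(self.scales) < 1:
            raise ValueError("at least one scale required")
        dims = {m.dim for m in self.scales}
        units = {m.unit for m in self.scales}
        if len(dims) != 1 or len(units) != 1:
            raise ValueError("all scales must share spatial dimension and unit")
        if self.descriptors is None:
            self.descriptors = [None] * len(self.scales)

    def __len__(self):
        return len(self.scales)

    def __getitem__(self, i):
        return self.scales[i]

    def as_particles(self) -> list[ParticleMeasure]:
        return [m if isinstance(m, ParticleMeasure) else m.to_particles() for m in self.scales]


# ---------------------------------------------------------------------------
# operations


def total_mass(mu: ParticleMeasure | LatticeMeasure) -> float:
    """Total mass M = integral of the measure = sum of the weights."""
    w = mu.weights if isinstance(mu, ParticleMeasure) else mu.site_weights
    return float(np.sum(w))


def disintegrate(mu: ParticleMeasure) -> dict:
    """Factor mu into spatial marginal and conditional feature laws.

    Returns ``{position tuple: (rho, ConditionalLaw)}`` with ``rho`` the
    summed weight at that exact position and law probabilities ``w_i / rho``.
    Coincident particles are grouped; distinct positions give single-atom
    laws.
    """
    out: dict = {}
    groups: dict = {}
    for i in range(mu.n):
        key = tuple(mu.positions[i])
        groups.setdefault(key, []).append(i)
    for key, idx in groups.items():
        w = mu.weights[idx]
        rho = float(w.sum())
        out[key] = (rho, ConditionalLaw(mu.features.take(idx), w / rho))
    return out


def reassemble(parts: dict, dim: int, unit: str = "um") -> ParticleMeasure:
    """Inverse of :func:`disintegrate` (up to particle order)."""
    positions, weights, feats = [], [], None
    for pos, (rho, law) in parts.items():
        for k in range(len(law.probs)):
            positions.append(pos)
            weights.append(rho * law.probs[k])
            fv = law.atoms[k]
            if feats is None:
                feats = (fv.kind, [])
            feats[1].append(fv.value)
    if not positions:
        return ParticleMeasure.empty(dim, unit=unit)
    kind, vals = feats
    f = Features.none(len(vals)) if kind == "none" else Features(kind, vals)
    return ParticleMeasure(np.array(positions, dtype=float), np.array(weights), f, unit)


def _fd_jacobian(phi: Callable, x: np.ndarray, h: float) -> np.ndarray:
    d = len(x)
    J = np.empty((d, d))
    for k in range(d):
        e = np.zeros(d)
        e[k] = h
        J[:, k] = (np.asarray(phi(x + e)) - np.asarray(phi(x - e))) / (2 * h)
    return J


def apply_action(
    phi: Callable[[np.ndarray], np.ndarray],
    mu: ParticleMeasure,
    jacobian: Callable[[np.ndarray], np.ndarray] | None = None,
    fd_step: float | None = None,
) -> ParticleMeasure:
    """Copy-and-paste varifold action of a diffeomorphism on a measure.

    Positions map through ``phi``; each weight is multiplied by
    ``|det d(phi)(x_i)|`` so that expanded tissue gains mass (total mass is
    *not* conserved); features are carried unchanged.

    ``jacobian`` is an analytic Jacobian callback; when absent, central
    finite differences with step ``fd_step`` (default 1e-4 times the domain
    diameter) are used.
    """
    if mu.n == 0:
        return mu
    if jacobian is None:
        if fd_step is None:
            span = np.ptp(mu.positions, axis=0)
            diam = float(np.linalg.norm(span))
            fd_step = 1e-4 * (diam if diam > 0 else 1.0)
        jacobian = lambda x: _fd_jacobian(phi, x, fd_step)  # noqa: E731
    new_pos = np.empty_like(mu.positions)
    new_w = np.empty_like(mu.weights)
    for i in range(mu.n):
        x = mu.positions[i]
        J = np.asarray(jacobian(x), dtype=float)
        if J.shape != (mu.dim, mu.dim) or not np.all(np.isfinite(J)):
            raise ValueError(f"non-finite or misshaped Jacobian at particle {i}")
        det = float(np.linalg.det(J))
        if not np.isfinite(det) or det == 0.0:
            raise ValueError(f"singular Jacobian at particle {i}")
        new_pos[i] = phi(x)
        new_w[i] = mu.weights[i] * abs(det)
    if not np.all(np.isfinite(new_pos)):
        raise ValueError("phi produced non-finite positions")
    return ParticleMeasure(new_pos, new_w, mu.features, mu.unit)


def image_to_measure(
    raster: np.ndarray,
    spacing: Sequence[float] | float = 1.0,
    origin: Sequence[float] | float = 0.0,
    unit: str = "pix",
) -> ParticleMeasure:
    """Convert a 2-d/3-d intensity raster to a pixel-particle measure.

    One particle per voxel center, weight = voxel volume, scalar feature =
    the intensity. This realizes dense images inside the measure framework
    so that image registration becomes a special case of measure matching.
    """
    arr = np.asarray(raster, dtype=float)
    if arr.size == 0:
        raise ValueError("empty raster")
    if arr.ndim not in (2, 3):
        raise ValueError("raster must be 2-d or 3-d")
    if not np.all(np.isfinite(arr)):
        raise ValueError("raster has non-finite intensities")
    d = arr.ndim
    spacing = np.broadcast_to(np.asarray(spacing, dtype=float), (d,))
    origin = np.broadcast_to(np.asarray(origin, dtype=float), (d,))
    grid = Grid(tuple(origin), tuple(spacing), arr.shape)
    vol = float(np.prod(spacing))
    return ParticleMeasure(
        grid.centers(),
        np.full(arr.size, vol),
        Features("scalar", arr.ravel()),
        unit,
    )


@dataclasses.dataclass(frozen=True)
class UniformRectangle:
    """Uniform spatial density on an axis-aligned rectangle [lo, hi]."""

    lo: tuple
    hi: tuple

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        lo = np.asarray(self.lo, dtype=float)
        hi = np.asarray(self.hi, dtype=float)
        if np.any(hi <= lo):
            raise ValueError("degenerate rectangle")
        return rng.uniform(lo, hi, size=(n, len(lo)))


@dataclasses.dataclass(frozen=True)
class GaussianMixtureDensity:
    """Gaussian-mixture spatial density (means (K,d), sds (K,), weights (K,))."""

    means: tuple
    sds: tuple
    mix: tuple

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        means = np.atleast_2d(np.asarray(self.means, dtype=float))
        sds = np.asarray(self.sds, dtype=float)
        mix = np.asarray(self.mix, dtype=float)
        mix = mix / mix.sum()
        comp = rng.choice(len(mix), size=n, p=mix)
        return means[comp] + rng.standard_normal((n, means.shape[1])) * sds[comp, None]


def sample_from_law(
    density,
    law: Union[ConditionalLaw, Callable[[np.ndarray], ConditionalLaw]],
    n: int,
    mass: float,
    seed: int,
    unit: str = "um",
) -> ParticleMeasure:
    """Draw n i.i.d. particles (x_i, f_i) from mu / M, each with weight M/n.

    The weighted empirical measure converges weakly to the continuum law as
    n grows (law of large numbers), which the varifold norm quantifies at
    the canonical Monte-Carlo rate n^{-1/2}.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not hasattr(density, "sample"):
        raise ValueError("density spec is not samplable (needs .sample(n, rng))")
    rng = np.random.default_rng(seed)
    pos = density.sample(n, rng)
    fixed = isinstance(law, ConditionalLaw)
    kinds = (law if fixed else law(pos[0])).atoms.kind
    if fixed and kinds not in ("none", "spike-times"):
        idx = rng.choice(len(law.probs), size=n, p=law.probs)
        values = law.atoms.as_matrix()[idx]
    else:
        values = []
        for i in range(n):
            li = law if fixed else law(pos[i])
            k = rng.choice(len(li.probs), p=li.probs)
            values.append(li.atoms[k].value)
    feats = Features.none(n) if kinds == "none" else Features(kinds, values)
    return ParticleMeasure(pos, np.full(n, mass / n), feats, unit)
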