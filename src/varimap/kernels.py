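"""Kernel machinery: Gaussian Green's functions, cumulative kernels,
lattice transition weights and varifold-kernel specifications.

Each deformation scale l carries an RKHS of vector fields with a diagonal
kernel g_l(x, y) id. We use non-normalized Gaussians

    g(x, y) = exp(-|x - y|^2 / (2 sigma^2)),        g(x, x) = 1,

parameterized either by sigma or by the full width at half maximum,
FWHM = 2 sqrt(2 ln 2) sigma. The hierarchical optimal control averages
Green's functions across scales through the cumulative kernel
gbar_l = sum_{j <= l} g_j; its derivatives up to third order enter the
particle costate dynamics, so all of them are exposed in closed form.

Spatial transition weights pi(x, Y) for lattice resampling are Gaussian
cell integrals (products of one-dimensional error-function integrals) or
nearest-center indicators.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy.special import erf

__all__ = [
    "GaussianKernel",
    "CumulativeKernel",
    "KernelHandle",
    "VarifoldKernelSpec",
    "fwhm_to_sigma",
    "sigma_to_fwhm",
    "greens_eval",
    "gaussian_cell_weight",
    "nearest_center",
]

_FWHM = 2.0 * np.sqrt(2.0 * np.log(2.0))

GREENS_ORDERS = ("value", "grad1", "jac12", "div12", "grad_div")


def fwhm_to_sigma(fwhm: float) -> float:
    return float(fwhm) / _FWHM


def sigma_to_fwhm(sigma: float) -> float:
    return float(sigma) * _FWHM


@dataclasses.dataclass(frozen=True)
class GaussianKernel:
    """Scalar Gaussian Green's function of one deformation scale."""

    sigma: float

    def __post_init__(self):
        if not self.sigma > 0:
            raise ValueError("sigma must be > 0")

    @classmethod
    def from_fwhm(cls, fwhm: float) -> "GaussianKernel":
        return cls(fwhm_to_sigma(fwhm))

    @property
    def fwhm(self) -> float:
        return sigma_to_fwhm(self.sigma)


def _gauss_order(sigma: float, v: np.ndarray, order: str):
    """Closed-form derivatives of g at difference v = x - y.

    grad1 is the gradient in the first argument; jac12 the mixed second
    derivative matrix d^2 g / dx dy; div12 its trace; grad_div the gradient
    of div12 with respect to the second argument.
    """
    v = np.asarray(v, dtype=float)
    d = v.shape[-1]
    s2 = sigma * sigma
    r2 = np.sum(v * v, axis=-1)
    e = np.exp(-0.5 * r2 / s2)
    if order == "value":
        return e
    if order == "grad1":
        return -(v / s2) * e[..., None]
    if order == "jac12":
        eye = np.eye(d)
        return (eye / s2 - np.einsum("...i,...j->...ij", v, v) / s2**2) * e[..., None, None]
    if order == "div12":
        return (d / s2 - r2 / s2**2) * e
    if order == "grad_div":
        return (v / s2**2) * ((d + 2) - r2 / s2)[..., None] * e[..., None]
    raise ValueError(f"unsupported derivative order {order!r}; one of {GREENS_ORDERS}")


def greens_eval(spec: GaussianKernel, x, y, order: str = "value"):
    """Evaluate g(x, y) or one of its closed-form derivatives.

    Broadcasts over leading axes; the trailing axis is the spatial
    dimension.
    """
    v = np.asarray(x, dtype=float) - np.asarray(y, dtype=float)
    if not np.all(np.isfinite(v)):
        raise ValueError("non-finite kernel inputs")
    return _gauss_order(spec.sigma, v, order)


class KernelHandle:
    """Sum of Gaussian components, evaluating all derivative orders."""

    def __init__(self, components: tuple[GaussianKernel, ...]):
        if len(components) == 0:
            raise ValueError("empty kernel handle")
        self.components = tuple(components)

    @property
    def sigmas(self) -> tuple[float, ...]:
        return tuple(k.sigma for k in self.components)

    def eval(self, x, y, order: str = "value"):
        v = np.asarray(x, dtype=float) - np.asarray(y, dtype=float)
        out = _gauss_order(self.components[0].sigma, v, order)
        for k in self.components[1:]:
            out = out + _gauss_order(k.sigma, v, order)
        return out

    def __call__(self, x, y):
        return self.eval(x, y, "value")


@dataclasses.dataclass(frozen=True)
class CumulativeKernel:
    """Per-scale Green's functions g_0 .. g_{lmax-1}, coarse to fine,
    with the cumulative sums gbar_l = sum_{j <= l} g_j used by the
    hierarchical control."""

    components: tuple[GaussianKernel, ...]

    def __post_init__(self):
        comps = tuple(self.components)
        if len(comps) < 1:
            raise ValueError("at least one scale required")
        object.__setattr__(self, "components", comps)

    @classmethod
    def from_fwhm(cls, fwhms) -> "CumulativeKernel":
        return cls(tuple(GaussianKernel.from_fwhm(f) for f in fwhms))

    @property
    def n_scales(self) -> int:
        return len(self.components)

    def scale(self, ell: int) -> GaussianKernel:
        return self.components[ell]

    def cumulative(self, ell: int, j: int | None = None) -> KernelHandle:
        """Handle for gbar_{min(ell, j)} = sum_{m <= min(ell, j)} g_m."""
        if j is None:
            j = ell
        if not (0 <= ell < self.n_scales and 0 <= j < self.n_scales):
            raise IndexError(f"scale index out of range: ({ell}, {j})")
        m = min(ell, j)
        return KernelHandle(self.components[: m + 1])


@dataclasses.dataclass(frozen=True)
class VarifoldKernelSpec:
    """Separable Gaussian varifold kernel: spatial width sigma_x and
    feature width sigma_f (None = featureless, feature factor identically
    1)."""

    sigma_x: float
    sigma_f: float | None = None

    def __post_init__(self):
        if not self.sigma_x > 0:
            raise ValueError("sigma_x must be > 0")
        if self.sigma_f is not None and not self.sigma_f > 0:
            raise ValueError("sigma_f must be > 0 or None")


def gaussian_cell_weight(sigma: float, x, lo, hi) -> np.ndarray:
    """Gaussian transition weight pi_sigma(x, Y) = int_Y N(x, sigma^2 I).

    ``lo``/``hi`` are the cell corners; +-inf entries make the cell
    unbounded along that axis (the all-infinite sentinel gives 1). The
    integral factorizes per axis through the Gaussian error integral.
    Broadcasts over leading axes of ``x``.
    """
    if not sigma > 0:
        raise ValueError("sigma must be > 0")
    x = np.atleast_1d(np.asarray(x, dtype=float))
    lo = np.broadcast_to(np.asarray(lo, dtype=float), x.shape[-1:])
    hi = np.broadcast_to(np.asarray(hi, dtype=float), x.shape[-1:])
    if np.any(hi <= lo):
        raise ValueError("degenerate cell: hi must exceed lo on every axis")
    s = sigma * np.sqrt(2.0)
    a = erf((hi - x) / s)
    b = erf((lo - x) / s)
    return np.prod(0.5 * (a - b), axis=-1)


def nearest_center(x, centers) -> int:
    """Index of the Euclidean-nearest center; ties go to the lowest index."""
    centers = np.atleast_2d(np.asarray(centers, dtype=float))
    if centers.shape[0] == 0:
        raise ValueError("empty center list")
    d2 = np.sum((centers - np.asarray(x, dtype=float)) ** 2, axis=1)
    return int(np.argmin(d2))
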