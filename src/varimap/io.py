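"""File formats: particle CSV tables, multiscale manifests, TOML configs.

Particle measures are stored as human-inspectable delimited tables with
header ``x0[,x1[,x2]],w,f0[,f1,...]``; positions and weights at 17
significant digits so round trips are bit-identical. Spike-time features
are one quoted, semicolon-separated increasing list per row. Multiscale
measures are a JSON manifest listing one CSV per scale together with the
feature kind and unit. Run configuration is TOML.
"""

from __future__ import annotations

import csv
import json
import pathlib
import warnings

import numpy as np

from .measures import Features, MultiscaleMeasure, ParticleMeasure

__all__ = [
    "read_particles",
    "write_particles",
    "read_raster",
    "read_manifest",
    "write_manifest",
    "load_config",
    "ConfigError",
    "write_run_log",
]


def _fmt(x: float) -> str:
    return format(float(x), ".17g")


def write_particles(mu: ParticleMeasure, path) -> None:
    path = pathlib.Path(path)
    kind = mu.features.kind
    with open(path, "w", newline="") as fh:
        wr = csv.writer(fh)
        if kind == "none":
            n_f = 0
        elif kind == "spike-times":
            n_f = 1
        else:
            n_f = mu.features.as_matrix().shape[1]
        header = [f"x{a}" for a in range(mu.dim)] + ["w"] + [f"f{k}" for k in range(n_f)]
        wr.writerow(header)
        for i in range(mu.n):
            row = [_fmt(v) for v in mu.positions[i]] + [_fmt(mu.weights[i])]
            if kind == "spike-times":
                row.append(";".join(_fmt(t) for t in mu.features.data[i]))
            elif kind == "complex-vector":
                row += [repr(complex(v)) for v in mu.features.data[i]]
            elif kind != "none":
                row += [_fmt(v) for v in mu.features.data[i]]
            wr.writerow(row)


def read_particles(path, kind: str | None = None, unit: str = "um") -> ParticleMeasure:
    """Read a particle CSV; ``kind`` overrides feature-kind inference.

    Inference: no f columns -> featureless; a single f column containing
    ';' -> spike trains; one f column -> scalar; several -> vector.
    Errors name the offending line.
    """
    path = pathlib.Path(path)
    with open(path, newline="") as fh:
        rd = csv.reader(fh)
        try:
            header = next(rd)
        except StopIteration:
            raise ValueError(f"{path}: empty file") from None
        rows = list(rd)
    header = [h.strip() for h in header]
    dim = sum(1 for h in header if h.startswith("x"))
    if dim not in (1, 2, 3) or "w" not in header:
        raise ValueError(f"{path}: bad header {header!r}; expected x0[,x1,x2],w,f0..")
    if header[:dim] != [f"x{a}" for a in range(dim)] or header[dim] != "w":
        raise ValueError(f"{path}: bad header {header!r}")
    f_cols = header[dim + 1:]
    if f_cols != [f"f{k}" for k in range(len(f_cols))]:
        raise ValueError(f"{path}: bad feature columns {f_cols!r}")

    pos, wts, feats = [], [], []
    for ln, row in enumerate(rows, start=2):
        if not row:
            continue
        if len(row) != len(header):
            raise ValueError(f"{path}: line {ln}: expected {len(header)} fields, got {len(row)}")
        try:
            pos.append([float(v) for v in row[:dim]])
            w = float(row[dim])
        except ValueError as exc:
            raise ValueError(f"{path}: line {ln}: {exc}") from None
        if not w > 0:
            raise ValueError(f"{path}: line {ln}: non-positive weight {w}")
        wts.append(w)
        feats.append(row[dim + 1:])

    n = len(wts)
    if kind is None:
        if not f_cols:
            kind = "none"
        elif len(f_cols) == 1 and any(";" in f[0] for f in feats):
            kind = "spike-times"
        elif any(any("j" in v or "(" in v for v in f) for f in feats):
            kind = "complex-vector"
        else:
            kind = "scalar" if len(f_cols) == 1 else "vector"
    try:
        if kind == "none":
            features = Features.none(n)
        elif kind == "spike-times":
            features = Features(
                "spike-times",
                [[float(t) for t in f[0].split(";")] if f[0] else [] for f in feats],
            )
        elif kind == "complex-vector":
            features = Features("complex-vector", [[complex(v) for v in f] for f in feats])
        else:
            features = Features(kind, [[float(v) for v in f] for f in feats])
    except ValueError as exc:
        raise ValueError(f"{path}: bad feature data: {exc}") from None
    if n == 0:
        return ParticleMeasure.empty(dim, kind if kind != "vector" else "none", unit)
    return ParticleMeasure(np.array(pos), np.array(wts), features, unit)


def read_raster(path, spacing=1.0, origin=0.0, unit: str = "pix") -> ParticleMeasure:
    """Load a grayscale PNG/TIFF raster as a pixel-particle measure.

    Color images are averaged to one channel; TIFF stacks come through
    tifffile and everything else through imageio.
    """
    path = pathlib.Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        arr = np.asarray(tifffile.imread(path), dtype=float)
    else:
        import imageio.v3 as iio

        arr = np.asarray(iio.imread(path), dtype=float)
    if arr.ndim == 3 and arr.shape[-1] in (3, 4):
        arr = arr[..., :3].mean(axis=-1)
    from .measures import image_to_measure

    return image_to_measure(arr, spacing=spacing, origin=origin, unit=unit)


def write_manifest(mu: MultiscaleMeasure, path) -> None:
    """Write a multiscale measure: JSON manifest + one CSV per scale,
    coarse to fine. Lattice scales are stored through their nonempty sites
    with reduced features."""
    path = pathlib.Path(path)
    stem = path.with_suffix("")
    entries = []
    parts = mu.as_particles()
    for ell, p in enumerate(parts):
        fname = f"{stem.name}_scale{ell}.csv"
        write_particles(p, path.parent / fname)
        entries.append({
            "file": fname,
            "feature_kind": p.features.kind,
            "descriptor": mu.descriptors[ell],
        })
    with open(path, "w") as fh:
        json.dump({"unit": parts[0].unit, "scales": entries}, fh, indent=2)


def read_manifest(path) -> MultiscaleMeasure:
    path = pathlib.Path(path)
    with open(path) as fh:
        doc = json.load(fh)
    scales, descriptors = [], []
    for entry in doc["scales"]:
        fpath = path.parent / entry["file"]
        if not fpath.exists():
            raise FileNotFoundError(f"manifest scale file missing: {fpath}")
        scales.append(read_particles(fpath, kind=entry.get("feature_kind"),
                                     unit=doc.get("unit", "um")))
        descriptors.append(entry.get("descriptor"))
    return MultiscaleMeasure(scales, descriptors)


class ConfigError(ValueError):
    """Raised with the full list of configuration schema violations."""


_SCHEMA = {
    "scales": {"fwhm"},
    "varifold": {"sigma_x", "sigma_f"},
    "match": {"alpha", "T", "max_iter", "grad_mode"},
    "renormalize": {"sigma", "grid", "features", "k", "n_types"},
    "simulate": {"kind", "intensity", "extent", "n_cells", "n_genes", "n_types",
                 "separation", "rna_per_cell", "layer_means", "layer_sd",
                 "momenta_scale", "steps"},
}

_DEFAULTS = {
    "match": {"alpha": 1.0, "T": 20, "max_iter": 200, "grad_mode": "adjoint"},
}


def load_config(path) -> dict:
    """Load and validate a TOML run configuration.

    Unknown sections or keys are rejected; all violations are reported at
    once. A non-monotone (fine-before-coarse) FWHM list only warns, since
    scale order is a convention, not a constraint.
    """
    import tomllib

    with open(path, "rb") as fh:
        cfg = tomllib.load(fh)
    errors = []
    for section, keys in cfg.items():
        if section not in _SCHEMA:
            errors.append(f"unknown section [{section}]")
            continue
        if not isinstance(keys, dict):
            errors.append(f"[{section}] must be a table")
            continue
        for key in keys:
            if key not in _SCHEMA[section]:
                errors.append(f"unknown key {section}.{key}")
    scales = cfg.get("scales", {})
    fwhm = scales.get("fwhm")
    if fwhm is not None:
        if not isinstance(fwhm, list) or not all(
                isinstance(v, (int, float)) and v > 0 for v in fwhm):
            errors.append("scales.fwhm must be a list of positive numbers")
        elif any(b > a for a, b in zip(fwhm, fwhm[1:])):
            warnings.warn("scales.fwhm is not coarse-to-fine (non-increasing)",
                          stacklevel=2)
    var = cfg.get("varifold", {})
    if isinstance(var, dict):
        for key in ("sigma_x", "sigma_f"):
            v = var.get(key)
            if v is not None and not (
                isinstance(v, list) and all(isinstance(s, (int, float)) and s > 0 for s in v)
            ):
                errors.append(f"varifold.{key} must be a list of positive numbers")
    m = cfg.get("match", {})
    if isinstance(m, dict):
        if "alpha" in m and not (isinstance(m["alpha"], (int, float)) and m["alpha"] > 0):
            errors.append("match.alpha must be > 0")
        if "T" in m and not (isinstance(m["T"], int) and m["T"] >= 1):
            errors.append("match.T must be an integer >= 1")
        if "grad_mode" in m and m["grad_mode"] not in (
                "adjoint", "autodiff", "fd", "finite-difference"):
            errors.append("match.grad_mode must be adjoint|autodiff|fd")
    if errors:
        raise ConfigError("invalid configuration:\n  " + "\n  ".join(errors))
    out = {k: dict(v) for k, v in cfg.items()}
    for section, defaults in _DEFAULTS.items():
        out.setdefault(section, {})
        for key, val in defaults.items():
            out[section].setdefault(key, val)
    return out


def write_run_log(path, **fields) -> None:
    """JSON log of a CLI run: parameters, seeds, versions, timings."""
    import time

    from . import __version__

    doc = {"varimap_version": __version__, "numpy_version": np.__version__,
           "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S")}
    doc.update(fields)
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=2, default=str)
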