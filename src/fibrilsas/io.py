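"""File formats: 1D curves, 2D patterns with geometry sidecars, fit recipes.

1D curves are 3-column whitespace text (q, I, sigma_I) with ``# key: value``
header lines carrying metadata; q is in 1/angstrom unless the header
declares ``q_unit: 1/nm``, in which case values are converted on read.
2D patterns are plain text matrices (or an HDF5 dataset when the path ends
in .h5/.hdf5) with a key-value geometry sidecar.  Fit recipes are INI files
with [init], [fixed], [bounds] and [options] sections.
"""

from __future__ import annotations

import configparser
import json
from pathlib import Path

import numpy as np

from fibrilsas.curves import Curve1D
from fibrilsas.fitting import FIT_KEYS, FitRecipe, FitResult
from fibrilsas.reduction import Geometry, Pattern2D

__all__ = [
    "read_curve", "write_curve", "read_geometry", "read_pattern",
    "read_recipe", "write_result",
]

_GEOMETRY_KEYS = ("beam_center_x", "beam_center_y", "pixel_size",
                  "distance", "wavelength")


def _parse_scalar(text: str):
    for cast in (int, float):
        try:
            return cast(text)
        except ValueError:
            pass
    if text.lower() in ("true", "false"):
        return text.lower() == "true"
    return text


def write_curve(curve: Curve1D, path: str | Path,
                overwrite: bool = True) -> None:
    """Write a curve as 3-column text with metadata header lines."""
    path = Path(path)
    if path.exists() and not overwrite:
        raise FileExistsError(f"{path} exists (pass overwrite=True)")
    lines = ["# q_unit: 1/angstrom"]
    for key, value in curve.metadata.items():
        if key == "q_unit":
            continue
        lines.append(f"# {key}: {value}")
    lines.append("# columns: q intensity sigma")
    sig = curve.sigma if curve.sigma is not None else np.zeros_like(curve.q)
    for q, i, s in zip(curve.q, curve.intensity, sig):
        lines.append(f"{q:.10e} {i:.10e} {s:.10e}")
    path.write_text("\n".join(lines) + "\n")


def read_curve(path: str | Path) -> Curve1D:
    """Read a 3-column text curve; malformed rows raise with line numbers.

    A third column of zeros (or a missing third column) means no
    uncertainties.  ``q_unit: 1/nm`` in the header converts q to 1/A.
    """
    path = Path(path)
    meta: dict = {}
    rows: list[tuple[float, float, float]] = []
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line.lstrip("#").strip()
            if ":" in body:
                key, _, value = body.partition(":")
                meta[key.strip()] = _parse_scalar(value.strip())
            continue
        parts = line.split()
        if len(parts) not in (2, 3):
            raise ValueError(f"{path}:{lineno}: expected 2 or 3 columns, "
                             f"got {len(parts)}")
        try:
            vals = [float(p) for p in parts]
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: non-numeric value ({exc})") from None
        rows.append((vals[0], vals[1], vals[2] if len(vals) == 3 else 0.0))
    if not rows:
        raise ValueError(f"{path}: no data rows")
    arr = np.array(rows)
    q, inten, sig = arr[:, 0], arr[:, 1], arr[:, 2]
    unit = str(meta.pop("q_unit", "1/angstrom")).lower().replace(" ", "")
    if unit in ("1/nm", "nm^-1", "nm-1"):
        q = q * 0.1
    elif unit not in ("1/angstrom", "1/a", "a^-1", "angstrom^-1"):
        raise ValueError(f"{path}: unrecognised q_unit '{unit}'")
    meta.pop("columns", None)
    sigma = sig if np.any(sig > 0) else None
    return Curve1D(q, inten, sigma, meta)


def read_geometry(path: str | Path) -> Geometry:
    """Read a key-value geometry sidecar; missing keys raise by name."""
    path = Path(path)
    values: dict = {}
    for raw in path.read_text().splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        for sep in ("=", ":"):
            if sep in line:
                key, _, value = line.partition(sep)
                values[key.strip()] = float(value.strip())
                break
    missing = [k for k in _GEOMETRY_KEYS if k not in values]
    if missing:
        raise KeyError(f"{path}: missing geometry key(s): {', '.join(missing)}")
    return Geometry(**{k: values[k] for k in _GEOMETRY_KEYS})


def read_pattern(path: str | Path, geometry_path: str | Path,
                 mask_path: str | Path | None = None) -> Pattern2D:
    """Read a 2D pattern (text matrix or HDF5 dataset) plus geometry.

    For HDF5 the dataset name defaults to ``intensity`` and may be given
    as ``file.h5:dataset``.  An optional mask file (text matrix, nonzero =
    valid) excludes pixels from every reduction.
    """
    path = str(path)
    if ".h5" in path or ".hdf5" in path:
        import h5py

        fname, _, dset = path.partition(":")
        with h5py.File(fname, "r") as fh:
            arr = np.asarray(fh[dset or "intensity"], dtype=float)
    else:
        arr = np.loadtxt(path, dtype=float)
    geometry = read_geometry(geometry_path)
    mask = None
    if mask_path is not None:
        mask = np.loadtxt(mask_path) != 0
    return Pattern2D(arr, geometry, mask)


def read_recipe(path: str | Path) -> FitRecipe:
    """Read a fit recipe from an INI file.

    Sections: ``[init]`` parameter values (plus ``gaussian_enabled``),
    ``[fixed]`` parameter names set to true, ``[bounds]`` ``key = lo, hi``
    pairs, ``[options]`` rel_error / qmin / qmax.
    """
    cp = configparser.ConfigParser()
    cp.optionxform = str  # parameter names are case sensitive
    read = cp.read(path)
    if not read:
        raise FileNotFoundError(path)
    init = {k: _parse_scalar(v) for k, v in cp.items("init")} if cp.has_section("init") else {}
    fixed = set()
    if cp.has_section("fixed"):
        for key, value in cp.items("fixed"):
            if str(value).lower() in ("1", "true", "yes"):
                fixed.add(key)
    bounds = {}
    if cp.has_section("bounds"):
        for key, value in cp.items("bounds"):
            lo, hi = (float(x) for x in value.replace(",", " ").split())
            bounds[key] = (lo, hi)
    rel_error, q_range = 0.02, None
    if cp.has_section("options"):
        opts = dict(cp.items("options"))
        rel_error = float(opts.get("rel_error", rel_error))
        if "qmin" in opts or "qmax" in opts:
            q_range = (float(opts.get("qmin", 0.0)),
                       float(opts.get("qmax", np.inf)))
    return FitRecipe(init=init, fixed=frozenset(fixed), bounds=bounds,
                     rel_error=rel_error, q_range=q_range)


def write_result(result: FitResult | dict, path: str | Path,
                 overwrite: bool = True) -> None:
    """Serialize a fit result as a flat JSON record (lengths in nm)."""
    path = Path(path)
    if path.exists() and not overwrite:
        raise FileExistsError(f"{path} exists (pass overwrite=True)")
    if isinstance(result, FitResult):
        record = dict(result.values)
        record.update({f"err_{k}": v for k, v in result.errors.items()
                       if v is not None})
        record["redchi"] = result.redchi
        record["success"] = result.success
        record["fixed"] = sorted(result.fixed)
    else:
        record = dict(result)
    path.write_text(json.dumps(record, indent=2, sort_keys=True) + "\n")
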