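"""Reduction of fibre-symmetric 2D scattering patterns to equatorial curves.

A wood fibre pattern is strongly anisotropic: the steep helical alignment
of the microfibrils concentrates their cross-sectional scattering into two
opposite equatorial arcs, sitting on an isotropic contribution from
non-oriented material.  The separation used here is:

1. azimuthal profiles I(phi) on thin q annuli;
2. a Gaussian fit around the equatorial maximum gives the sector centre
   phi0, and the profile *minimum* at each q approximates the isotropic
   component;
3. radial averaging over two opposite 25-degree sectors centred on phi0;
4. subtraction of the isotropic component from the sector average.

Conventions: phi is measured counter-clockwise from the detector +x axis
(columns), in degrees; with the fibre axis vertical the equatorial maxima
sit near phi = 0/180.  The exact mapping q = 4 pi sin(theta)/lambda is used
(no small-angle approximation).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

from fibrilsas.curves import Curve1D

__all__ = [
    "Geometry", "Pattern2D", "AzimuthalProfile", "AzimuthalPeak",
    "azimuthal_profile", "fit_azimuthal_peak", "isotropic_component",
    "sector_average", "equatorial_excess", "merge_curves",
]


@dataclass(frozen=True)
class Geometry:
    """Detector geometry mapping pixels to scattering coordinates.

    ``beam_center_x``/``beam_center_y`` in pixels (x = column, y = row),
    ``pixel_size`` and ``distance`` in mm, ``wavelength`` in angstrom.
    """

    beam_center_x: float
    beam_center_y: float
    pixel_size: float
    distance: float
    wavelength: float

    def __post_init__(self) -> None:
        for name in ("pixel_size", "distance", "wavelength"):
            if getattr(self, name) <= 0:
                raise ValueError(f"geometry {name} must be > 0")


@dataclass
class Pattern2D:
    """2D detector image plus geometry and an optional pixel mask.

    ``mask`` is True for *valid* pixels; masked-out pixels are excluded
    from every reduction.
    """

    intensity: np.ndarray
    geometry: Geometry
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.intensity.ndim != 2:
            raise ValueError("intensity must be a 2D array")
        if self.mask is None:
            self.mask = np.ones(self.intensity.shape, dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.intensity.shape:
                raise ValueError("mask shape must match intensity")
        self._q_map: np.ndarray | None = None
        self._phi_map: np.ndarray | None = None

    def q_map(self) -> np.ndarray:
        """Magnitude of the scattering vector per pixel, 1/angstrom."""
        if self._q_map is None:
            g = self.geometry
            ny, nx = self.intensity.shape
            y, x = np.mgrid[0:ny, 0:nx]
            r = np.hypot((x - g.beam_center_x), (y - g.beam_center_y)) * g.pixel_size
            theta = 0.5 * np.arctan2(r, g.distance)
            self._q_map = 4.0 * np.pi * np.sin(theta) / g.wavelength
        return self._q_map

    def phi_map(self) -> np.ndarray:
        """Azimuth per pixel, degrees CCW from +x, in [0, 360)."""
        if self._phi_map is None:
            g = self.geometry
            ny, nx = self.intensity.shape
            y, x = np.mgrid[0:ny, 0:nx]
            phi = np.degrees(np.arctan2(y - g.beam_center_y, x - g.beam_center_x))
            self._phi_map = np.mod(phi, 360.0)
        return self._phi_map


@dataclass
class AzimuthalProfile:
    """Mean intensity versus azimuth on one q annulus."""

    q_center: float
    q_halfwidth: float
    phi: np.ndarray        # bin centres, degrees
    intensity: np.ndarray  # nan where the bin had no valid pixels
    counts: np.ndarray     # valid pixels per bin

    @property
    def valid(self) -> np.ndarray:
        return self.counts > 0


@dataclass(frozen=True)
class AzimuthalPeak:
    """Gaussian description of the equatorial maximum of an I(phi) profile.

    ``phi0`` reduced mod 180 (fibre symmetry); ``converged`` False flags a
    degenerate or failed fit, in which case ``baseline`` falls back to the
    profile minimum.
    """

    phi0: float
    width: float
    baseline: float
    amplitude: float
    converged: bool


def azimuthal_profile(pattern: Pattern2D, q_center: float, q_halfwidth: float,
                      n_phi: int = 72) -> AzimuthalProfile:
    """Bin the annulus |q - q_center| <= q_halfwidth into azimuth bins."""
    qm = pattern.q_map()
    sel = pattern.mask & (np.abs(qm - q_center) <= q_halfwidth)
    if not np.any(sel):
        raise ValueError(
            f"empty annulus: no valid pixels with |q - {q_center}| <= {q_halfwidth}")
    phi = pattern.phi_map()[sel]
    inten = pattern.intensity[sel]
    edges = np.linspace(0.0, 360.0, n_phi + 1)
    idx = np.clip(np.digitize(phi, edges) - 1, 0, n_phi - 1)
    counts = np.bincount(idx, minlength=n_phi)
    sums = np.bincount(idx, weights=inten, minlength=n_phi)
    with np.errstate(invalid="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    centres = 0.5 * (edges[:-1] + edges[1:])
    return AzimuthalProfile(q_center, q_halfwidth, centres, means, counts)


def _wrapped_double_gaussian(phi, amp, phi0, sd, baseline):
    """Two Gaussians 180 degrees apart, wrapped on the circle."""
    out = np.full_like(phi, baseline, dtype=float)
    for centre in (phi0, phi0 + 180.0):
        d = np.mod(phi - centre + 180.0, 360.0) - 180.0
        out += amp * np.exp(-0.5 * (d / sd) ** 2)
    return out


def fit_azimuthal_peak(profile: AzimuthalProfile) -> AzimuthalPeak:
    """Fit a Gaussian pair (fibre symmetry) plus constant baseline to I(phi).

    The baseline is anchored near the profile minimum (the isotropic
    level); the returned centre is reduced mod 180.  A flat or
    non-converging profile yields ``converged=False`` with the baseline at
    the profile minimum.
    """
    ok = profile.valid & np.isfinite(profile.intensity)
    if ok.sum() < 10:
        raise ValueError("need at least 10 valid azimuth bins to fit")
    phi, inten = profile.phi[ok], profile.intensity[ok]
    lo, hi = float(inten.min()), float(inten.max())
    if hi - lo <= 1e-12 * max(abs(hi), 1.0):
        return AzimuthalPeak(phi0=float(phi[0] % 180.0), width=0.0,
                             baseline=lo, amplitude=0.0, converged=False)
    p0 = [hi - lo, float(phi[np.argmax(inten)] % 180.0), 15.0, lo]
    try:
        popt, _ = curve_fit(
            _wrapped_double_gaussian, phi, inten, p0=p0,
            bounds=([0.0, -90.0, 1.0, -np.inf], [np.inf, 270.0, 90.0, np.inf]),
            maxfev=10000,
        )
    except RuntimeError:
        return AzimuthalPeak(phi0=p0[1], width=p0[2], baseline=lo,
                             amplitude=p0[0], converged=False)
    amp, phi0, sd, baseline = popt
    return AzimuthalPeak(phi0=float(phi0 % 180.0), width=float(sd),
                         baseline=float(baseline), amplitude=float(amp),
                         converged=True)


def _radial_bin(pattern: Pattern2D, sel: np.ndarray, q_grid: np.ndarray,
                meta: dict) -> Curve1D:
    """Mean intensity of selected pixels in annular q bins."""
    q_grid = np.asarray(q_grid, dtype=float)
    edges = np.empty(q_grid.size + 1)
    edges[1:-1] = 0.5 * (q_grid[:-1] + q_grid[1:])
    edges[0] = max(q_grid[0] - (edges[1] - q_grid[0]), 0.0)
    edges[-1] = q_grid[-1] + (q_grid[-1] - edges[-2])
    qm = pattern.q_map()[sel]
    inten = pattern.intensity[sel]
    idx = np.digitize(qm, edges) - 1
    keep = (idx >= 0) & (idx < q_grid.size)
    idx, inten = idx[keep], inten[keep]
    counts = np.bincount(idx, minlength=q_grid.size)
    sums = np.bincount(idx, weights=inten, minlength=q_grid.size)
    sums2 = np.bincount(idx, weights=inten**2, minlength=q_grid.size)
    has = counts > 0
    mean = sums[has] / counts[has]
    var = np.maximum(sums2[has] / counts[has] - mean**2, 0.0)
    sem = np.sqrt(var / counts[has])
    sem[sem <= 0] = np.nan
    sigma = np.where(np.isfinite(sem), sem, np.nanmax(sem) if np.any(np.isfinite(sem)) else 1.0)
    sigma = np.maximum(sigma, 1e-12)
    return Curve1D(q_grid[has], mean, sigma, meta)


def isotropic_component(pattern: Pattern2D, q_grid: np.ndarray,
                        n_phi: int = 72) -> Curve1D:
    """Isotropic contribution: the azimuthal-profile minimum at each q.

    Equatorial arcs vanish away from the equator, so the minimum over
    azimuth approximates the non-oriented background under the arcs.
    """
    q_grid = np.asarray(q_grid, dtype=float)
    edges = np.empty(q_grid.size + 1)
    edges[1:-1] = 0.5 * (q_grid[:-1] + q_grid[1:])
    edges[0] = max(q_grid[0] - (edges[1] - q_grid[0]), 0.0)
    edges[-1] = q_grid[-1] + (q_grid[-1] - edges[-2])
    qs, vals, sigs = [], [], []
    for lo, hi, qc in zip(edges[:-1], edges[1:], q_grid):
        try:
            prof = azimuthal_profile(pattern, 0.5 * (lo + hi), 0.5 * (hi - lo), n_phi)
        except ValueError:
            continue
        ok = prof.valid & np.isfinite(prof.intensity)
        if not np.any(ok):
            continue
        i = int(np.nanargmin(np.where(ok, prof.intensity, np.nan)))
        qs.append(qc)
        vals.append(prof.intensity[i])
        sigs.append(max(np.sqrt(max(prof.intensity[i], 0.0) / max(prof.counts[i], 1)), 1e-12))
    if not qs:
        raise ValueError("no q bin of the grid contains valid pixels")
    return Curve1D(np.array(qs), np.array(vals), np.array(sigs),
                   {"component": "isotropic", "n_phi": n_phi})


def sector_average(pattern: Pattern2D, phi0: float, q_grid: np.ndarray,
                   width: float = 25.0, both: bool = True) -> Curve1D:
    """Radial average over the sector(s) of given angular width.

    Averages the two opposite sectors centred at phi0 and phi0 + 180 by
    default (fibre symmetry); ``both=False`` restricts to one sector.
    width = 360 reproduces the full azimuthal average.
    """
    if not (0 < width <= 360):
        raise ValueError("sector width must be in (0, 360]")
    phim = pattern.phi_map()
    half = 0.5 * width
    d1 = np.abs(np.mod(phim - phi0 + 180.0, 360.0) - 180.0)
    sel = d1 <= half
    if both:
        d2 = np.abs(np.mod(phim - phi0 - 180.0 + 180.0, 360.0) - 180.0)
        sel |= d2 <= half
    sel &= pattern.mask
    if not np.any(sel):
        raise ValueError("sector contains no valid pixels")
    meta = {"component": "sector", "phi0_deg": float(phi0),
            "sector_width_deg": float(width), "both_sectors": both}
    return _radial_bin(pattern, sel, q_grid, meta)


def equatorial_excess(sector: Curve1D, iso: Curve1D) -> Curve1D:
    """Sector average minus isotropic component on the sector q grid.

    The isotropic curve is interpolated onto the sector grid when the
    grids differ; uncertainties propagate in quadrature.  Negative values
    are legitimate noise and are kept.
    """
    iso_i = np.interp(sector.q, iso.q, iso.intensity)
    if iso.sigma is not None:
        iso_s = np.interp(sector.q, iso.q, iso.sigma)
    else:
        iso_s = np.zeros_like(sector.q)
    sec_s = sector.sigma if sector.sigma is not None else np.zeros_like(sector.q)
    sigma = np.sqrt(sec_s**2 + iso_s**2)
    sigma = np.maximum(sigma, 1e-12)
    meta = dict(sector.metadata)
    meta["component"] = "equatorial_excess"
    meta["iso_interpolated"] = not (iso.q.size == sector.q.size
                                    and np.allclose(iso.q, sector.q))
    return Curve1D(sector.q, sector.intensity - iso_i, sigma, meta)


def merge_curves(curves: list[Curve1D], n_bins: int = 200) -> Curve1D:
    """Merge curves from different detector distances onto one log grid.

    Curves are ordered by starting q; each successive curve is scaled by
    the least-squares factor matching the previous merged data on the
    overlap region, then all points are rebinned onto a log-spaced grid.
    """
    if not curves:
        raise ValueError("no curves to merge")
    if len(curves) == 1:
        return curves[0]
    ordered = sorted(curves, key=lambda c: c.q[0])
    q_all = ordered[0].q.copy()
    i_all = ordered[0].intensity.copy()
    s_all = (ordered[0].sigma.copy() if ordered[0].sigma is not None
             else np.full_like(q_all, np.nan))
    factors = [1.0]
    for cur in ordered[1:]:
        lo, hi = max(q_all.min(), cur.q.min()), min(q_all.max(), cur.q.max())
        if hi <= lo:
            factor = 1.0
        else:
            osel = (cur.q >= lo) & (cur.q <= hi)
            ref = np.interp(cur.q[osel], q_all, i_all)
            num = float(np.dot(ref, cur.intensity[osel]))
            den = float(np.dot(cur.intensity[osel], cur.intensity[osel]))
            factor = num / den if den > 0 else 1.0
        factors.append(factor)
        q_all = np.concatenate([q_all, cur.q])
        i_all = np.concatenate([i_all, factor * cur.intensity])
        s_all = np.concatenate([
            s_all,
            factor * cur.sigma if cur.sigma is not None
            else np.full_like(cur.q, np.nan),
        ])
    order = np.argsort(q_all)
    q_all, i_all, s_all = q_all[order], i_all[order], s_all[order]
    edges = np.geomspace(q_all[0], q_all[-1] * (1 + 1e-12), n_bins + 1)
    idx = np.clip(np.digitize(q_all, edges) - 1, 0, n_bins - 1)
    counts = np.bincount(idx, minlength=n_bins)
    has = counts > 0
    mean_q = np.bincount(idx, weights=q_all, minlength=n_bins)[has] / counts[has]
    mean_i = np.bincount(idx, weights=i_all, minlength=n_bins)[has] / counts[has]
    with np.errstate(invalid="ignore"):
        var = np.bincount(idx, weights=np.nan_to_num(s_all**2), minlength=n_bins)[has]
    mean_s = np.sqrt(var) / counts[has]
    sigma = np.where(mean_s > 0, mean_s, np.nan)
    if np.all(np.isnan(sigma)):
        sigma = None
    else:
        fill = np.nanmax(sigma)
        sigma = np.where(np.isfinite(sigma), sigma, fill)
    # guard against duplicate q after averaging
    uq, ui = np.unique(mean_q, return_index=True)
    return Curve1D(uq, mean_i[ui], None if sigma is None else sigma[ui],
                   {"component": "merged", "scale_factors": factors})
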