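"""Synthetic scattering data with known ground truth.

Generates the three kinds of data the analysis consumes: 1D equatorial
curves drawn from the intensity model with multiplicative Gaussian noise
(matching the 2%-relative-error weighting convention), fibre-symmetric 2D
detector patterns (isotropic component plus equatorial Gaussian arcs,
Poisson counting noise), and equatorial WAXS profiles (three crystalline
Gaussians, a broad amorphous Gaussian and a linear background).  All
randomness flows from an explicit seed.

What these emulate — and what they do not: curves follow the fitted model
family exactly, so recovery tests probe the estimator, not model adequacy;
patterns have ideal geometry with no instrumental smearing, detector
point-spread, flat-field error or parasitic background.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from fibrilsas import model, presets
from fibrilsas.curves import Curve1D
from fibrilsas.reduction import Geometry, Pattern2D

__all__ = [
    "PatternSpec", "simulate_curve", "simulate_pattern2d",
    "simulate_drying_series", "simulate_waxs_curve", "default_geometry",
]


def simulate_curve(params: dict | model.ModelParams, q: np.ndarray,
                   rel_noise: float = 0.02, seed: int | None = 0,
                   metadata: dict | None = None) -> Curve1D:
    """Model curve with multiplicative Gaussian noise.

    I_obs = I_model * (1 + eps), eps ~ N(0, rel_noise); the stored sigma is
    rel_noise * I_model (the true relative error, as assumed by the
    weighting convention).  rel_noise = 0 returns the exact model curve.
    """
    if rel_noise < 0:
        raise ValueError("rel_noise must be >= 0")
    if isinstance(params, model.ModelParams):
        p = params
        flat = model.params_to_dict(params)
    else:
        p = model.params_from_dict(params)
        flat = dict(params)
    q = np.asarray(q, dtype=float)
    ideal = model.total_intensity(q, p)
    if rel_noise > 0:
        rng = np.random.default_rng(seed)
        obs = ideal * (1.0 + rel_noise * rng.standard_normal(q.size))
        sigma = rel_noise * ideal
    else:
        obs = ideal.copy()
        sigma = None
    meta = {"generator": "simulate_curve", "rel_noise": rel_noise,
            "seed": seed}
    meta.update({f"truth_{k}": v for k, v in flat.items()})
    if metadata:
        meta.update(metadata)
    return Curve1D(q, obs, sigma, meta)


def default_geometry(shape: tuple[int, int] = (128, 128)) -> Geometry:
    """SANS-like geometry: 6 A neutrons, 1.5 m distance, 7.5 mm pixels.

    Covers q up to ~0.3 1/A at the detector corner for a 128x128 array,
    bracketing the 0.15 1/A interfibrillar correlation peak.
    """
    ny, nx = shape
    return Geometry(
        beam_center_x=(nx - 1) / 2.0,
        beam_center_y=(ny - 1) / 2.0,
        pixel_size=7.5,
        distance=1500.0,
        wavelength=6.0,
    )


def _default_iso(q):
    """Smooth isotropic radial profile (Lorentzian decay on a floor)."""
    return 20.0 / (1.0 + (np.asarray(q) / 0.05) ** 2) + 2.0


def _default_equatorial(q):
    """Equatorial radial profile: correlation-peak-like Gaussian ridge."""
    q = np.asarray(q)
    return 30.0 * np.exp(-0.5 * ((q - 0.15) / 0.06) ** 2)


@dataclass
class PatternSpec:
    """Recipe for one synthetic fibre-symmetric detector pattern.

    Expected pixel intensity is
    ``exposure * [iso(q) + eq(q) * (G(phi; phi0, sd) + G(phi; phi0+180, sd))]``
    with wrapped Gaussian arcs, optionally Poisson-sampled.  ``exposure``
    is the photon budget: doubling it halves the relative counting noise.
    """

    shape: tuple[int, int] = (128, 128)
    geometry: Geometry | None = None
    iso_profile: Callable = field(default=lambda q: _default_iso(q))
    equatorial_profile: Callable = field(default=lambda q: _default_equatorial(q))
    phi0: float = 0.0            # arc centre, degrees
    arc_sd: float = 12.0         # arc width SD, degrees
    exposure: float = 30.0       # expected counts multiplier (photon budget)
    poisson: bool = True


def simulate_pattern2d(spec: PatternSpec, seed: int | None = 0) -> Pattern2D:
    """Render a synthetic fibre pattern (counts) from its spec."""
    geom = spec.geometry or default_geometry(spec.shape)
    holder = Pattern2D(np.zeros(spec.shape), geom)
    qm, phim = holder.q_map(), holder.phi_map()
    arcs = np.zeros(spec.shape)
    for centre in (spec.phi0, spec.phi0 + 180.0):
        d = np.mod(phim - centre + 180.0, 360.0) - 180.0
        arcs += np.exp(-0.5 * (d / spec.arc_sd) ** 2)
    expected = spec.exposure * (spec.iso_profile(qm)
                                + spec.equatorial_profile(qm) * arcs)
    expected = np.maximum(expected, 0.0)
    if spec.poisson:
        rng = np.random.default_rng(seed)
        counts = rng.poisson(expected).astype(float)
    else:
        counts = expected
    return Pattern2D(counts, geom)


def simulate_drying_series(schedule: list[dict] | None = None,
                           q: np.ndarray | None = None,
                           rel_noise: float = 0.02,
                           seed: int = 0) -> list[Curve1D]:
    """Sequence of noisy curves following a drying parameter ramp.

    Default schedule: interfibrillar spacing 4.2 -> 3.3 nm, diameter
    2.5 -> 2.2 nm, rising pore power-law scale, on the short-distance
    SAXS q range.  Per-step seeds derive deterministically from ``seed``.
    """
    if schedule is None:
        schedule = presets.drying_schedule()
    if q is None:
        q = np.geomspace(0.03, 0.5, 150)
    rng = np.random.default_rng(seed)
    sub = rng.integers(0, 2**31 - 1, size=len(schedule))
    return [
        simulate_curve(truth, q, rel_noise, int(s), {"series_index": i})
        for i, (truth, s) in enumerate(zip(schedule, sub))
    ]


def simulate_waxs_curve(peaks: dict | None = None,
                        q: np.ndarray | None = None,
                        rel_noise: float = 0.0,
                        seed: int | None = 0) -> Curve1D:
    """Equatorial WAXS profile built from reflection d/L parameters.

    Each reflection contributes a Gaussian at q = 2 pi / d whose SD follows
    from the Scherrer integral breadth Delta-q = 2 pi K / L via
    SD = Delta-q / sqrt(2 pi); a broad amorphous Gaussian and a linear
    background are added.  Noise-free by default.
    """
    if peaks is None:
        peaks = presets.hardwood_waxs_peaks()
    if q is None:
        q = np.linspace(0.5, 2.25, 600)
    q = np.asarray(q, dtype=float)
    K = peaks.get("scherrer_K", 1.0)
    curve = np.zeros_like(q)
    meta = {"generator": "simulate_waxs_curve", "scherrer_K": K}
    for name, ref in peaks["reflections"].items():
        center = 2.0 * np.pi / (ref["d"] * 10.0)            # 1/A
        breadth = 2.0 * np.pi * K / (ref["L"] * 10.0)       # integral breadth
        sd = breadth / np.sqrt(2.0 * np.pi)
        curve += ref["amplitude"] * np.exp(-0.5 * ((q - center) / sd) ** 2)
        meta[f"truth_q_{name}"] = center
        meta[f"truth_sd_{name}"] = sd
    am = peaks["amorphous"]
    curve += am["amplitude"] * np.exp(-0.5 * ((q - am["center"]) / am["sd"]) ** 2)
    bg = peaks["background"]
    curve += bg["slope"] * q + bg["intercept"]
    sigma = None
    if rel_noise > 0:
        rng = np.random.default_rng(seed)
        curve = curve * (1.0 + rel_noise * rng.standard_normal(q.size))
        sigma = np.maximum(rel_noise * np.abs(curve), 1e-12)
    return Curve1D(q, curve, sigma, meta)
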