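"""Equatorial small-angle scattering model for hexagonally packed cellulose
microfibrils.

The microfibrils of the wood secondary cell wall are modelled as infinitely
long circular cylinders of polydisperse radius, arranged on a 2D hexagonal
lattice with paracrystalline distortion of the second kind.  The equatorial
intensity is

    I(q) = A * I_cyl(q) + B * exp(-q^2 / (2 sigma^2)) + C * q^(-alpha)

where the Gaussian term (centred at q = 0) absorbs scattering from larger
pores and unresolved features and the power law describes surface scattering
from pores and lumina.  I_cyl combines the cylinder cross-section form
factor with the orientation-averaged paracrystalline lattice factor,

    I_cyl(q) = < f^2 >_R  -  < f >_R^2  +  < f >_R^2 * Z~(q)

with radius averages <.>_R taken over a truncated Gaussian radius
distribution and Z~(q) the azimuthally averaged two-factor lattice term.
Below the first minimum q0 of Z~ the lattice factor is continued as the
constant Z~(q0), suppressing the unphysical paracrystalline upturn at low q.

Internal units are angstroms (lengths) and 1/angstrom (q) throughout;
the flat parameter mapping used for fitting and serialization reports
lengths in nm (see :func:`params_from_dict`).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.special import j1

__all__ = [
    "RadiusDistribution",
    "LatticeConfig",
    "ModelParams",
    "ModifiedLattice",
    "cylinder_amplitude",
    "radius_quadrature",
    "lattice_factor",
    "psi_averaged_Z",
    "reduced_psi_averaged_Z",
    "turning_point",
    "reduced_turning_point",
    "i_cyl",
    "total_intensity",
    "evaluate",
    "params_from_dict",
    "params_to_dict",
]


# -----------------------------------------------------------------------
# parameter containers
# -----------------------------------------------------------------------

@dataclass(frozen=True)
class RadiusDistribution:
    """Gaussian distribution of the cylinder (microfibril) radius.

    Parameters
    ----------
    mean_radius : float
        Mean radius R-bar in angstrom.
    sd : float
        Standard deviation Delta-R in angstrom; 0 collapses the
        distribution to a single radius.
    n_points : int
        Number of equally spaced quadrature nodes (odd), default 11.
    truncation_k : float
        Half-width of the node interval in units of sd.
    """

    mean_radius: float
    sd: float = 0.0
    n_points: int = 11
    truncation_k: float = 3.0

    def __post_init__(self) -> None:
        if self.mean_radius <= 0:
            raise ValueError(f"mean_radius must be > 0, got {self.mean_radius}")
        if self.sd < 0:
            raise ValueError(f"radius sd must be >= 0, got {self.sd}")
        if self.n_points < 1 or self.n_points % 2 == 0:
            raise ValueError(f"n_points must be odd and >= 1, got {self.n_points}")
        if self.truncation_k <= 0:
            raise ValueError("truncation_k must be > 0")


@dataclass(frozen=True)
class LatticeConfig:
    """Distorted hexagonal arrangement of cylinder centres.

    ``spacing`` is the centre-to-centre distance a (angstrom) and
    ``distortion`` the paracrystalline SD Delta-a (angstrom) of the lattice
    vector lengths (distortion of the second kind: fluctuations accumulate,
    destroying long-range order).  ``psi_points`` sets the uniform grid on
    [0, 2 pi) used for the orientational average over the lattice azimuth.
    """

    spacing: float
    distortion: float
    psi_points: int = 1001

    def __post_init__(self) -> None:
        if self.spacing <= 0:
            raise ValueError(f"lattice spacing must be > 0, got {self.spacing}")
        if self.distortion < 0:
            raise ValueError(f"lattice distortion must be >= 0, got {self.distortion}")
        if self.psi_points < 3:
            raise ValueError("psi_points must be >= 3")

    @property
    def distortion_ratio(self) -> float:
        return self.distortion / self.spacing


@dataclass(frozen=True)
class ModelParams:
    """Full parameter set of the equatorial intensity model.

    ``scale_A``, ``scale_B``/``sigma`` and ``scale_C``/``alpha`` weight the
    cylinder-lattice, low-q Gaussian and power-law terms.  When
    ``gaussian_enabled`` is False the B term is omitted entirely (used for
    wet-softwood SAXS where no such contribution is needed).
    """

    scale_A: float
    radius: RadiusDistribution
    lattice: LatticeConfig
    scale_B: float = 0.0
    sigma: float = 0.02
    scale_C: float = 0.0
    alpha: float = 4.0
    gaussian_enabled: bool = True

    def __post_init__(self) -> None:
        for name in ("scale_A", "scale_B", "scale_C"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.gaussian_enabled and self.sigma <= 0:
            raise ValueError("sigma must be > 0 when the Gaussian term is enabled")
        if self.alpha <= 0:
            raise ValueError("alpha must be > 0")


@dataclass(frozen=True)
class ModifiedLattice:
    """Turning point of the low-q lattice-factor modification.

    ``q0`` is the first local minimum of the psi-averaged lattice factor and
    ``plateau`` its value there; below q0 the lattice factor is replaced by
    the constant plateau, which keeps the total intensity continuous at q0.
    """

    q0: float
    plateau: float


# -----------------------------------------------------------------------
# form factor and radius quadrature
# -----------------------------------------------------------------------

def cylinder_amplitude(q, R: float):
    """Cross-section scattering amplitude of an infinite cylinder.

    f(q, R) = pi R^2 * 2 J1(qR) / (qR), the 2D Fourier transform of a disc
    of radius R; f(0, R) = pi R^2 (the disc area).  Contrast and
    number-density prefactors are absorbed into the model scale A.
    R = 0 (a clipped quadrature node of a wide radius distribution) gives 0.
    """
    if R < 0:
        raise ValueError(f"radius must be >= 0, got {R}")
    q = np.asarray(q, dtype=float)
    if np.any(q < 0):
        raise ValueError("q must be >= 0")
    x = q * R
    area = np.pi * R * R
    with np.errstate(invalid="ignore", divide="ignore"):
        amp = np.where(x > 0, 2.0 * j1(np.where(x > 0, x, 1.0)) / np.where(x > 0, x, 1.0), 1.0)
    return area * amp


def radius_quadrature(dist: RadiusDistribution) -> tuple[np.ndarray, np.ndarray]:
    """Nodes and weights for averaging over the Gaussian radius distribution.

    ``n_points`` equally spaced nodes on
    [max(0, R - k*dR), R + k*dR]; negative lower bound is clipped to 0.
    Weights are proportional to the Gaussian density at each node and
    renormalized to sum to exactly 1.  dR = 0 gives the single node R.
    """
    if dist.sd == 0.0 or dist.n_points == 1:
        return np.array([dist.mean_radius]), np.array([1.0])
    lo = max(0.0, dist.mean_radius - dist.truncation_k * dist.sd)
    hi = dist.mean_radius + dist.truncation_k * dist.sd
    nodes = np.linspace(lo, hi, dist.n_points)
    z = (nodes - dist.mean_radius) / dist.sd
    w = np.exp(-0.5 * z * z)
    w /= w.sum()
    return nodes, w


# -----------------------------------------------------------------------
# paracrystalline lattice factor
# -----------------------------------------------------------------------

_PSI_1 = 0.0
_PSI_2 = np.pi / 3.0  # hexagonal basis vectors at 60 degrees


def _single_factor(g, qa_cos):
    """One paracrystalline factor Z_k = (1-g^2)/(1 - 2 g cos(.) + g^2)."""
    return (1.0 - g * g) / (1.0 - 2.0 * g * np.cos(qa_cos) + g * g)


def lattice_factor(q, psi, lattice: LatticeConfig):
    """Two-factor paracrystalline lattice term Z1*Z2 at azimuth psi.

    Each hexagonal basis direction contributes
    Z_k = (1 - g^2) / (1 - 2 g cos(q a cos(psi - psi_k)) + g^2)
    with disorder damping g = exp(-q^2 Delta-a^2 / 2) and psi_1 = 0,
    psi_2 = pi/3.  Broadcasts over numpy arrays in q and psi.
    """
    q = np.asarray(q, dtype=float)
    psi = np.asarray(psi, dtype=float)
    if np.any(q <= 0):
        raise ValueError("q must be > 0")
    g = np.exp(-0.5 * (q * lattice.distortion) ** 2)
    qa = q * lattice.spacing
    z1 = _single_factor(g, qa * np.cos(psi - _PSI_1))
    z2 = _single_factor(g, qa * np.cos(psi - _PSI_2))
    return z1 * z2


def reduced_psi_averaged_Z(qa, distortion_ratio: float, psi_points: int = 1001):
    """psi-averaged lattice factor in reduced units.

    The average depends on the dimensionless pair (q*a, Delta-a/a) only;
    this is the scale-free workhorse behind :func:`psi_averaged_Z` and the
    turning-point search.  ``qa`` may be an array.
    """
    qa = np.atleast_1d(np.asarray(qa, dtype=float))
    if np.any(qa <= 0):
        raise ValueError("q*a must be > 0")
    psi = np.linspace(0.0, 2.0 * np.pi, psi_points, endpoint=False)
    g = np.exp(-0.5 * (qa * distortion_ratio) ** 2)[:, None]
    qa_col = qa[:, None]
    z1 = _single_factor(g, qa_col * np.cos(psi - _PSI_1)[None, :])
    z2 = _single_factor(g, qa_col * np.cos(psi - _PSI_2)[None, :])
    return (z1 * z2).mean(axis=1)


def psi_averaged_Z(q, lattice: LatticeConfig):
    """Orientational average of the lattice factor over the psi grid.

    Arithmetic mean of Z1*Z2 over ``lattice.psi_points`` uniformly spaced
    azimuths on [0, 2 pi), reflecting the assumption that the rotation of
    the crystals about the cylinder axis is uniform.
    """
    q = np.asarray(q, dtype=float)
    scalar = q.ndim == 0
    out = reduced_psi_averaged_Z(
        np.atleast_1d(q) * lattice.spacing,
        lattice.distortion_ratio,
        lattice.psi_points,
    )
    return float(out[0]) if scalar else out


# turning-point searches repeat with identical reduced parameters during a
# fit series; memoise on the (rounded) reduced pair
_TP_CACHE: dict[tuple[float, int], tuple[float, float]] = {}
_TP_CACHE_MAX = 4096


def reduced_turning_point(distortion_ratio: float, psi_points: int = 1001) -> tuple[float, float]:
    """First local minimum of the reduced psi-averaged lattice factor.

    Returns ``(q0*a, plateau)``.  The averaged factor diverges towards low
    q*a, falls to a first minimum and then rises into the principal
    interference maximum near q*a = 2 pi; the minimum is bracketed on a
    coarse scan and refined with a bounded scalar minimisation.
    """
    if distortion_ratio <= 0:
        raise ValueError("turning point requires distortion > 0")
    key = (round(float(distortion_ratio), 12), psi_points)
    hit = _TP_CACHE.get(key)
    if hit is not None:
        return hit

    xs = np.linspace(0.1, 9.0, 446)  # step 0.02 in q*a
    zs = reduced_psi_averaged_Z(xs, distortion_ratio, psi_points)
    interior = np.flatnonzero((zs[1:-1] < zs[:-2]) & (zs[1:-1] <= zs[2:])) + 1
    if interior.size == 0:
        raise ValueError(
            f"no lattice-factor minimum found for distortion ratio {distortion_ratio}"
        )
    i = int(interior[0])
    res = minimize_scalar(
        lambda x: float(reduced_psi_averaged_Z(x, distortion_ratio, psi_points)[0]),
        bounds=(xs[i - 1], xs[i + 1]),
        method="bounded",
        options={"xatol": 1e-10},
    )
    out = (float(res.x), float(res.fun))
    if len(_TP_CACHE) >= _TP_CACHE_MAX:
        _TP_CACHE.clear()
    _TP_CACHE[key] = out
    return out


def turning_point(lattice: LatticeConfig) -> ModifiedLattice:
    """Locate the low-q turning point q0 of the averaged lattice factor.

    q0*a depends on the distortion ratio Delta-a/a alone, so the search is
    done once in reduced units and rescaled by the lattice spacing.
    """
    qa0, plateau = reduced_turning_point(lattice.distortion_ratio, lattice.psi_points)
    return ModifiedLattice(q0=qa0 / lattice.spacing, plateau=plateau)


def _modified_Z(q: np.ndarray, lattice: LatticeConfig) -> np.ndarray:
    """psi-averaged lattice factor with constant continuation below q0."""
    tp = turning_point(lattice)
    z = np.empty_like(q)
    above = q >= tp.q0
    if np.any(above):
        z[above] = psi_averaged_Z(q[above], lattice)
    z[~above] = tp.plateau
    return z


# -----------------------------------------------------------------------
# composite intensity
# -----------------------------------------------------------------------

def i_cyl(q, radius: RadiusDistribution, lattice: LatticeConfig):
    """Intensity of polydisperse cylinders on the distorted hexagonal lattice.

    I_cyl = [<f^2> - <f>^2 + <f>^2 Z~(q)] / <f(0)^2> with radius averages
    from :func:`radius_quadrature` and Z~ the low-q-modified orientation
    average of the lattice factor.  The normalisation by the mean squared
    forward amplitude <f(0)^2> = <(pi R^2)^2> makes I_cyl dimensionless and
    O(1), so the fitted scale A is comparable in magnitude to the Gaussian
    and power-law scales.
    """
    q = np.asarray(q, dtype=float)
    scalar = q.ndim == 0
    qv = np.atleast_1d(q)
    if np.any(qv <= 0):
        raise ValueError("q must be > 0")
    nodes, w = radius_quadrature(radius)
    f = np.empty((qv.size, nodes.size))
    for k, R in enumerate(nodes):
        f[:, k] = cylinder_amplitude(qv, R)
    mean_f = f @ w
    mean_f2 = (f * f) @ w
    norm = float(np.dot((np.pi * nodes**2) ** 2, w))
    if lattice.distortion > 0:
        z = _modified_Z(qv, lattice)
    else:
        z = psi_averaged_Z(qv, lattice)
    out = (mean_f2 - mean_f**2 + mean_f**2 * z) / norm
    return float(out[0]) if scalar else out


def total_intensity(q, params: ModelParams):
    """Total equatorial model intensity I(q).

    A * I_cyl + (optional) B * exp(-q^2/(2 sigma^2)) + C * q^(-alpha);
    q = 0 is rejected because of the power-law divergence.
    """
    q = np.asarray(q, dtype=float)
    scalar = q.ndim == 0
    qv = np.atleast_1d(q)
    if np.any(qv <= 0):
        raise ValueError("q must be > 0 (power-law term diverges at q = 0)")
    out = params.scale_A * np.atleast_1d(i_cyl(qv, params.radius, params.lattice))
    if params.gaussian_enabled and params.scale_B > 0:
        out = out + params.scale_B * np.exp(-0.5 * (qv / params.sigma) ** 2)
    if params.scale_C > 0:
        out = out + params.scale_C * qv ** (-params.alpha)
    return float(out[0]) if scalar else out


# -----------------------------------------------------------------------
# flat parameter mapping (fitting / serialization / plugin entry point)
# -----------------------------------------------------------------------

#: keys of the flat parameter mapping; lengths in nm on this surface
PARAM_KEYS = (
    "scale_A", "scale_B", "sigma", "scale_C", "alpha",
    "d_mean", "dR_rel", "a", "da_rel", "gaussian_enabled",
)


def params_from_dict(d: dict, *, n_radius: int = 11, truncation_k: float = 3.0,
                     psi_points: int = 1001) -> ModelParams:
    """Build :class:`ModelParams` from the flat nm-based key-value mapping.

    ``d_mean`` is the mean microfibril *diameter* in nm (as reported in
    results tables), ``dR_rel`` the relative radius SD, ``a`` the lattice
    spacing in nm and ``da_rel`` the relative lattice distortion.
    """
    mean_radius = float(d["d_mean"]) * 10.0 / 2.0
    radius = RadiusDistribution(
        mean_radius=mean_radius,
        sd=float(d.get("dR_rel", 0.0)) * mean_radius,
        n_points=n_radius,
        truncation_k=truncation_k,
    )
    spacing = float(d["a"]) * 10.0
    lattice = LatticeConfig(
        spacing=spacing,
        distortion=float(d.get("da_rel", 0.0)) * spacing,
        psi_points=psi_points,
    )
    return ModelParams(
        scale_A=float(d.get("scale_A", 1.0)),
        radius=radius,
        lattice=lattice,
        scale_B=float(d.get("scale_B", 0.0)),
        sigma=float(d.get("sigma", 0.02)),
        scale_C=float(d.get("scale_C", 0.0)),
        alpha=float(d.get("alpha", 4.0)),
        gaussian_enabled=bool(d.get("gaussian_enabled", True)),
    )


def params_to_dict(p: ModelParams) -> dict:
    """Flatten :class:`ModelParams` to the nm-based key-value mapping."""
    return {
        "scale_A": p.scale_A,
        "scale_B": p.scale_B,
        "sigma": p.sigma,
        "scale_C": p.scale_C,
        "alpha": p.alpha,
        "d_mean": 2.0 * p.radius.mean_radius / 10.0,
        "dR_rel": p.radius.sd / p.radius.mean_radius,
        "a": p.lattice.spacing / 10.0,
        "da_rel": p.lattice.distortion_ratio,
        "gaussian_enabled": p.gaussian_enabled,
    }


def evaluate(q, params: dict):
    """Single-entry model function: q array + flat parameter mapping.

    Suitable for registration as a plugin model in SAS fitting frameworks
    that expect an ``Iq(q, **params)``-style callable.
    """
    return total_intensity(q, params_from_dict(params))
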