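"""Reference parameter sets for wood scattering curves.

Flat nm-based parameter mappings (see :mod:`fibrilsas.model`) describing
typical equatorial curves of wet wood: a SANS-like softwood curve with a
pronounced interfibrillar correlation peak near q = 0.15 1/A, a SAXS-like
softwood curve dominated by the microfibril cross-section shoulder (no
low-q Gaussian term), and equatorial WAXS peak parameters of dry hardwood
cellulose I-beta.  These serve as generator truths for the synthetic-data
module and as sensible fit initialisations.
"""

from __future__ import annotations

__all__ = [
    "wet_softwood_sans",
    "wet_softwood_saxs",
    "hardwood_waxs_peaks",
    "drying_schedule",
]


def wet_softwood_sans() -> dict:
    """Wet softwood (pine-like) equatorial SANS parameters.

    Interfibrillar spacing a = 4.21 nm with 27.1% paracrystalline
    distortion, mean microfibril diameter 2.04 nm with 20% relative radius
    polydispersity; the low-q Gaussian and a steep power law are both
    present.
    """
    return {
        "scale_A": 1.7,
        "d_mean": 2.04,
        "dR_rel": 0.2,
        "a": 4.21,
        "da_rel": 0.271,
        "scale_B": 2.4,
        "sigma": 1.48e-2,
        "scale_C": 0.31e-7,
        "alpha": 4.34,
        "gaussian_enabled": True,
    }


def wet_softwood_saxs() -> dict:
    """Wet softwood (pine-like) equatorial SAXS parameters.

    Mean diameter 2.51 nm with 20.7% radius polydispersity, spacing
    3.75 nm with 41% distortion; the Gaussian term is disabled (wet
    softwood SAXS needs none).
    """
    return {
        "scale_A": 1.5e3,
        "d_mean": 2.51,
        "dR_rel": 0.207,
        "a": 3.75,
        "da_rel": 0.41,
        "scale_B": 0.0,
        "sigma": 0.03,
        "scale_C": 0.04e-3,
        "alpha": 4.2,
        "gaussian_enabled": False,
    }


def hardwood_waxs_peaks() -> dict:
    """Equatorial WAXS peak parameters of dry hardwood (birch-like).

    Per reflection of cellulose I-beta: lattice spacing d_hkl (nm) and
    crystal size L_hkl (nm); peak centres follow q = 2 pi / d and Gaussian
    SDs follow from the Scherrer integral breadth 2 pi K / L with K = 1.
    Amplitudes, the broad amorphous Gaussian near 1.4 1/A and the linear
    background are generator choices at realistic relative magnitudes.
    """
    return {
        "reflections": {
            "1-10": {"d": 0.5780, "L": 2.95, "amplitude": 40.0},
            "110": {"d": 0.5211, "L": 4.73, "amplitude": 30.0},
            "200": {"d": 0.3891, "L": 3.09, "amplitude": 100.0},
        },
        "amorphous": {"center": 1.4, "sd": 0.35, "amplitude": 25.0},
        "background": {"slope": -2.0, "intercept": 8.0},
        "scherrer_K": 1.0,
    }


def drying_schedule(n_steps: int = 12) -> list[dict]:
    """Parameter ramp emulating in-situ drying of a softwood sample.

    Over the series the interfibrillar spacing contracts by ~20%
    (4.2 -> 3.3 nm), the microfibril diameter shrinks (2.5 -> 2.2 nm), the
    cylinder-term scale A decays and the pore power-law scale C rises, as
    water leaves the spaces between microfibrils.  The power-law exponent
    is held at 4 as appropriate for the short-distance q range.
    """
    import numpy as np

    fr = np.linspace(0.0, 1.0, n_steps)
    out = []
    for t in fr:
        out.append({
            "scale_A": 1.5e3 * (1.0 - 0.7 * t),
            "d_mean": 2.5 - 0.3 * t,
            "dR_rel": 0.21,
            "a": 4.2 - 0.9 * t,
            "da_rel": 0.35,
            "scale_B": 0.3e3 * t,
            "sigma": 0.075,
            "scale_C": 0.04e-3 + 3.0e-3 * t,
            "alpha": 4.0,
            "gaussian_enabled": True,
        })
    return out
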