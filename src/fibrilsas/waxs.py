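"""Equatorial WAXS peak fitting and Scherrer crystal sizes.

The equatorial wide-angle profile of dry wood between q = 0.5 and
2.25 1/A is described by three Gaussian peaks for the 1-10, 110 and 200
reflections of cellulose I-beta, one broad Gaussian near q = 1.4 1/A for
the amorphous background (and unresolved reflections), and a linear term.
From each crystalline peak the lattice spacing d = 2 pi / q and the
Scherrer crystal size L = 2 pi K / Delta-q are derived, with Delta-q the
*integral* breadth of the peak (area / height; SD * sqrt(2 pi) for a
Gaussian) and K = 1 by default.  L values are lower-limit estimates: lattice
distortions also broaden the peaks, and no instrumental-broadening
deconvolution is applied.
"""

from __future__ import annotations

from dataclasses import dataclass

import lmfit
import numpy as np

from fibrilsas.curves import Curve1D

__all__ = ["REFLECTIONS", "Reflection", "WaxsPeaks", "fit_waxs",
           "scherrer_size", "d_spacing", "integral_breadth"]

#: fitted reflections of cellulose I-beta with initial centres (1/A)
REFLECTIONS = ("1-10", "110", "200")
_INIT_CENTERS = {"1-10": 1.09, "110": 1.21, "200": 1.61}

FIT_WINDOW = (0.5, 2.25)  # 1/A


def d_spacing(q_hkl: float) -> float:
    """Lattice spacing d = 2 pi / q, in nm for q in 1/angstrom."""
    if q_hkl <= 0:
        raise ValueError("q must be > 0")
    return 2.0 * np.pi / q_hkl / 10.0


def integral_breadth(sd: float) -> float:
    """Integral breadth (area/height) of a Gaussian of standard deviation sd."""
    if sd <= 0:
        raise ValueError("Gaussian sd must be > 0")
    return sd * np.sqrt(2.0 * np.pi)


def scherrer_size(breadth: float, K: float = 1.0) -> float:
    """Scherrer crystal size L = 2 pi K / Delta-q, in nm for Delta-q in 1/A."""
    if breadth <= 0:
        raise ValueError("integral breadth must be > 0")
    return 2.0 * np.pi * K / breadth / 10.0


@dataclass(frozen=True)
class Reflection:
    """Fitted crystalline peak and its derived quantities."""

    name: str
    center: float      # 1/A
    sd: float          # Gaussian SD, 1/A
    amplitude: float
    d: float           # nm
    breadth: float     # integral breadth, 1/A
    L: float           # nm


@dataclass
class WaxsPeaks:
    """Result of an equatorial WAXS profile fit.

    ``reflections`` maps reflection name to :class:`Reflection`;
    ``ordered`` is False when the fitted centres violate the expected
    ascending order 1-10 < 110 < 200.
    """

    reflections: dict
    amorphous: dict
    background: dict
    scherrer_K: float
    redchi: float
    success: bool
    ordered: bool

    def to_record(self) -> dict:
        """Flat record with per-reflection d_hkl and L_hkl in nm."""
        rec = {"scherrer_K": self.scherrer_K, "redchi": self.redchi,
               "success": self.success, "ordered": self.ordered}
        for name, r in self.reflections.items():
            rec[f"q_{name}"] = r.center
            rec[f"d_{name}"] = r.d
            rec[f"L_{name}"] = r.L
        return rec


def _waxs_model(pars, q):
    out = pars["bg_slope"] * q + pars["bg_intercept"]
    for name in ("p0", "p1", "p2", "am"):
        out = out + pars[f"{name}_amp"] * np.exp(
            -0.5 * ((q - pars[f"{name}_center"]) / pars[f"{name}_sd"]) ** 2)
    return out


def fit_waxs(curve: Curve1D, K: float = 1.0) -> WaxsPeaks:
    """Fit the three-peak + amorphous + linear model on [0.5, 2.25] 1/A.

    The curve must cover the fit window.  Least-squares residuals are
    unweighted in intensity, so the derived d and L are invariant under an
    overall intensity scaling of the input.
    """
    lo, hi = FIT_WINDOW
    if curve.q.min() > lo + 1e-9 or curve.q.max() < hi - 1e-9:
        raise ValueError(
            f"curve must cover the fit window [{lo}, {hi}] 1/A, "
            f"got [{curve.q.min():.3g}, {curve.q.max():.3g}]")
    win = curve.crop(lo, hi)
    q, inten = win.q, win.intensity
    scale = float(np.percentile(inten, 95))
    scale = scale if scale > 0 else 1.0

    pars = lmfit.Parameters()
    for i, name in enumerate(REFLECTIONS):
        c = _INIT_CENTERS[name]
        pars.add(f"p{i}_center", value=c, min=c - 0.12, max=c + 0.12)
        pars.add(f"p{i}_sd", value=0.08, min=0.005, max=0.4)
        pars.add(f"p{i}_amp", value=0.5 * scale, min=0.0)
    pars.add("am_center", value=1.4, min=1.1, max=1.7)
    pars.add("am_sd", value=0.35, min=0.1, max=1.0)
    pars.add("am_amp", value=0.3 * scale, min=0.0)
    pars.add("bg_slope", value=0.0)
    pars.add("bg_intercept", value=float(np.percentile(inten, 5)))

    out = lmfit.minimize(lambda p: _waxs_model(p, q) - inten, pars,
                         method="leastsq")

    reflections: dict[str, Reflection] = {}
    for i, name in enumerate(REFLECTIONS):
        center = float(out.params[f"p{i}_center"].value)
        sd = float(out.params[f"p{i}_sd"].value)
        amp = float(out.params[f"p{i}_amp"].value)
        br = integral_breadth(sd)
        reflections[name] = Reflection(
            name=name, center=center, sd=sd, amplitude=amp,
            d=d_spacing(center), breadth=br, L=scherrer_size(br, K))
    centres = [reflections[n].center for n in REFLECTIONS]
    return WaxsPeaks(
        reflections=reflections,
        amorphous={"center": float(out.params["am_center"].value),
                   "sd": float(out.params["am_sd"].value),
                   "amplitude": float(out.params["am_amp"].value)},
        background={"slope": float(out.params["bg_slope"].value),
                    "intercept": float(out.params["bg_intercept"].value)},
        scherrer_K=K,
        redchi=float(out.redchi),
        success=bool(out.success),
        ordered=bool(centres[0] < centres[1] < centres[2]),
    )
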