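"""Weighted least-squares fitting of the equatorial intensity model.

Fits minimise sum of [(I_data - I_model) / (w * I_data)]^2 with a relative
weight w (default 0.02, i.e. a 2% error assigned to every intensity point),
using bounded Levenberg-Marquardt through lmfit.  Recipes capture the
fixed-parameter conventions used for different kinds of curves: radius
polydispersity fixed for SANS, the low-q Gaussian disabled for wet-softwood
SAXS, and the drying-series constraints (power-law exponent fixed to 4,
sigma bounded above by 0.08).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import lmfit
import numpy as np

from fibrilsas import model, presets
from fibrilsas.curves import Curve1D

__all__ = ["FitRecipe", "FitResult", "fit_curve", "fit_series",
           "sans_recipe", "saxs_recipe", "drying_recipe"]

#: parameters that can vary in a fit, in recipe order (flat nm-based keys)
FIT_KEYS = ("scale_A", "d_mean", "dR_rel", "a", "da_rel",
            "scale_B", "sigma", "scale_C", "alpha")

#: default parameter bounds; generous but physical
DEFAULT_BOUNDS: dict[str, tuple[float, float]] = {
    "scale_A": (0.0, np.inf),
    "d_mean": (0.5, 8.0),       # nm
    "dR_rel": (0.01, 0.6),
    "a": (1.0, 10.0),           # nm
    "da_rel": (0.02, 0.9),
    "scale_B": (0.0, np.inf),
    "sigma": (1e-3, 0.2),       # 1/A
    "scale_C": (0.0, np.inf),
    "alpha": (3.0, 5.5),
}


@dataclass
class FitRecipe:
    """Declarative description of one fit.

    ``init`` is a flat nm-based parameter mapping (initial values and the
    ``gaussian_enabled`` flag); ``fixed`` names parameters to hold at their
    initial value; ``bounds`` overrides :data:`DEFAULT_BOUNDS` per key.
    ``rel_error`` is the relative intensity error used as fit weight and
    ``q_range`` an optional (qmin, qmax) restriction in 1/angstrom.
    """

    init: dict
    fixed: frozenset = frozenset()
    bounds: dict = field(default_factory=dict)
    rel_error: float = 0.02
    q_range: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        self.fixed = frozenset(self.fixed)
        unknown = self.fixed - set(FIT_KEYS)
        if unknown:
            raise ValueError(f"unknown fixed parameter(s): {sorted(unknown)}")
        if self.rel_error <= 0:
            raise ValueError("rel_error must be > 0")
        for key in FIT_KEYS:
            lo, hi = self.bound(key)
            v = self.init.get(key)
            if v is not None and not (lo <= v <= hi):
                raise ValueError(
                    f"initial {key}={v} outside bounds ({lo}, {hi})")

    def bound(self, key: str) -> tuple[float, float]:
        return self.bounds.get(key, DEFAULT_BOUNDS[key])

    def with_init(self, init: dict) -> "FitRecipe":
        return replace(self, init=dict(init))


@dataclass
class FitResult:
    """Outcome of one model fit.

    ``values`` holds the best-fit flat parameter mapping (lengths in nm);
    ``errors`` the 1-SD uncertainties from the Jacobian covariance at the
    optimum, absent (None) for fixed parameters; ``redchi`` the reduced
    chi-square under the relative-error weighting.
    """

    values: dict
    errors: dict
    redchi: float
    success: bool
    fixed: frozenset
    nfev: int = 0
    message: str = ""

    @property
    def params(self) -> model.ModelParams:
        return model.params_from_dict(self.values)


def _make_parameters(recipe: FitRecipe) -> lmfit.Parameters:
    gaussian = bool(recipe.init.get("gaussian_enabled", True))
    pars = lmfit.Parameters()
    for key in FIT_KEYS:
        lo, hi = recipe.bound(key)
        value = float(recipe.init.get(key, 0.5 * (lo + min(hi, lo + 4))))
        vary = key not in recipe.fixed
        if key in ("scale_B", "sigma") and not gaussian:
            vary = False
        pars.add(key, value=value, min=lo, max=hi, vary=vary)
    return pars


def _model_from_pars(pars, gaussian_enabled: bool) -> model.ModelParams:
    d = {k: float(pars[k].value) for k in FIT_KEYS}
    d["gaussian_enabled"] = gaussian_enabled
    return model.params_from_dict(d)


def fit_curve(curve: Curve1D, recipe: FitRecipe) -> FitResult:
    """Fit the equatorial model to one curve under the given recipe.

    Deterministic given data and recipe.  Non-convergence is reported in
    ``success``/``message`` with the last iterate returned, never raised.
    """
    if recipe.q_range is not None:
        curve = curve.crop(*recipe.q_range)
    gaussian = bool(recipe.init.get("gaussian_enabled", True))
    pars = _make_parameters(recipe)
    n_free = sum(p.vary for p in pars.values())
    if len(curve) < 3 * n_free:
        raise ValueError(
            f"need at least {3 * n_free} points for {n_free} free parameters, "
            f"got {len(curve)}")

    q, data = curve.q, curve.intensity
    weight = recipe.rel_error * data

    def residual(p):
        mp = _model_from_pars(p, gaussian)
        return (data - model.total_intensity(q, mp)) / weight

    out = lmfit.minimize(residual, pars, method="leastsq")

    values = {k: float(out.params[k].value) for k in FIT_KEYS}
    values["gaussian_enabled"] = gaussian
    errors = {
        k: (float(out.params[k].stderr)
            if out.params[k].vary and out.params[k].stderr is not None
            else None)
        for k in FIT_KEYS
    }
    return FitResult(
        values=values,
        errors=errors,
        redchi=float(out.redchi),
        success=bool(out.success),
        fixed=recipe.fixed,
        nfev=int(out.nfev),
        message=str(out.message),
    )


def fit_series(curves: list[Curve1D], recipe: FitRecipe) -> list[FitResult]:
    """Fit an ordered series of curves (e.g. in-situ drying).

    Each fit warm-starts from the previous *converged* best fit; a fit that
    fails to converge is kept in the output flagged unsuccessful and does
    not poison subsequent starts.
    """
    results: list[FitResult] = []
    current = recipe
    for curve in curves:
        res = fit_curve(curve, current)
        results.append(res)
        if res.success:
            warm = dict(res.values)
            for k in recipe.fixed:          # fixed values never drift
                warm[k] = recipe.init[k]
            current = recipe.with_init(warm)
    return results


# -----------------------------------------------------------------------
# recipes
# -----------------------------------------------------------------------

def sans_recipe(init: dict | None = None, *, rel_error: float = 0.02,
                q_range: tuple[float, float] | None = None) -> FitRecipe:
    """Standard recipe for equatorial SANS curves.

    The relative radius polydispersity is fixed at its initial value
    (default 0.2): the form-factor shoulder is too weak in SANS to
    constrain it.
    """
    base = presets.wet_softwood_sans()
    if init:
        base.update(init)
    return FitRecipe(init=base, fixed=frozenset({"dR_rel"}),
                     rel_error=rel_error, q_range=q_range)


def saxs_recipe(init: dict | None = None, *, rel_error: float = 0.02,
                q_range: tuple[float, float] | None = None) -> FitRecipe:
    """Standard recipe for wet-softwood equatorial SAXS curves.

    All structural parameters free; the low-q Gaussian term is disabled.
    """
    base = presets.wet_softwood_saxs()
    base["gaussian_enabled"] = False
    if init:
        base.update(init)
    return FitRecipe(init=base, rel_error=rel_error, q_range=q_range)


def drying_recipe(init: dict | None = None, *, rel_error: float = 0.02,
                  q_range: tuple[float, float] | None = None) -> FitRecipe:
    """Recipe for drying-series SAXS over a limited q range.

    The power-law exponent alpha is fixed to 4 and sigma is bounded above
    by 0.08: with only the short-detector-distance q range these would
    otherwise be unstable.
    """
    base = presets.drying_schedule(2)[0]
    if init:
        base.update(init)
    base["alpha"] = 4.0
    return FitRecipe(
        init=base,
        fixed=frozenset({"alpha"}),
        bounds={"sigma": (1e-3, 0.08)},
        rel_error=rel_error,
        q_range=q_range,
    )
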