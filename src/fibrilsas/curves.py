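"""1D scattering-curve container shared by all modules."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["Curve1D"]


@dataclass
class Curve1D:
    """A (q, I, sigma_I) scattering curve.

    ``q`` is strictly increasing, in 1/angstrom; ``sigma`` is the 1-SD
    intensity uncertainty (optional).  ``metadata`` carries provenance
    (sector centre/width, units, generator truth, ...) as flat key-value
    pairs and travels through file I/O.
    """

    q: np.ndarray
    intensity: np.ndarray
    sigma: np.ndarray | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.q = np.asarray(self.q, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.q.ndim != 1 or self.q.shape != self.intensity.shape:
            raise ValueError("q and intensity must be 1D arrays of equal length")
        if self.q.size >= 2 and not np.all(np.diff(self.q) > 0):
            raise ValueError("q must be strictly increasing")
        if self.sigma is not None:
            self.sigma = np.asarray(self.sigma, dtype=float)
            if self.sigma.shape != self.q.shape:
                raise ValueError("sigma must match q in length")
            if np.any(self.sigma <= 0):
                raise ValueError("sigma values must be > 0 where present")

    def __len__(self) -> int:
        return self.q.size

    def crop(self, qmin: float | None = None, qmax: float | None = None) -> "Curve1D":
        """Restrict the curve to qmin <= q <= qmax (either bound optional)."""
        sel = np.ones(self.q.size, dtype=bool)
        if qmin is not None:
            sel &= self.q >= qmin
        if qmax is not None:
            sel &= self.q <= qmax
        return Curve1D(
            self.q[sel],
            self.intensity[sel],
            None if self.sigma is None else self.sigma[sel],
            dict(self.metadata),
        )
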