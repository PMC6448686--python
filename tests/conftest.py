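import numpy as np
import pytest

from fibrilsas import presets


@pytest.fixture(scope="session")
def sans_truth():
    """Wet-softwood SANS-like truth parameters (correlation peak at 0.15)."""
    return presets.wet_softwood_sans()


@pytest.fixture(scope="session")
def saxs_truth():
    """Wet-softwood SAXS-like truth parameters (no low-q Gaussian term)."""
    return presets.wet_softwood_saxs()


@pytest.fixture(scope="session")
def sans_q():
    return np.geomspace(0.005, 0.35, 200)


@pytest.fixture(scope="session")
def saxs_q():
    return np.geomspace(0.01, 0.5, 200)


def perturbed_start(truth: dict, seed: int, frac: float = 0.2,
                    keys=None) -> dict:
    """Truth parameters with each (free) value perturbed by +/- frac."""
    rng = np.random.default_rng(seed)
    init = dict(truth)
    if keys is None:
        keys = [k for k in ("scale_A", "d_mean", "dR_rel", "a", "da_rel",
                            "scale_B", "sigma", "scale_C", "alpha")
                if truth.get(k)]
    for k in keys:
        init[k] = truth[k] * (1.0 + frac * rng.uniform(-1.0, 1.0))
    init["alpha"] = float(np.clip(init.get("alpha", 4.0), 3.0, 5.5))
    return init
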