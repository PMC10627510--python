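import numpy as np
import pytest

from rafpa import DoseGrid, ModelParams, Variant
from rafpa.fitting import METHODS_BOUNDS


@pytest.fixture
def ca_default() -> ModelParams:
    """Default cellular context: strongly autoinhibited, sub-K_dim RAF."""
    return ModelParams(
        K_A=10.0, K_dim=0.1, K_d=0.1, raf_total=0.04, variant=Variant.CA
    )


@pytest.fixture
def unified_default() -> ModelParams:
    return ModelParams(
        K_A=10.0, K_dim=0.1, K_d=0.1, f=1.0, g=1.0,
        raf_total=0.04, variant=Variant.UNIFIED,
    )


@pytest.fixture
def sweep_grid() -> DoseGrid:
    return DoseGrid.log(1e-4, 1e2, 10)


def sample_params(rng: np.random.Generator, variant: Variant) -> ModelParams:
    """Log-uniform parameter draw within the fitting search bounds,
    respecting the variant's neutral pins."""

    def lu(lo, hi):
        return 10 ** rng.uniform(np.log10(lo), np.log10(hi))

    kw = dict(
        K_A=lu(*METHODS_BOUNDS["K_A"]),
        K_dim=lu(*METHODS_BOUNDS["K_dim"]),
        K_d=lu(*METHODS_BOUNDS["K_d"]),
        f=lu(*METHODS_BOUNDS["f"]),
        g=lu(*METHODS_BOUNDS["g"]),
        raf_total=lu(*METHODS_BOUNDS["raf_total"]),
        variant=variant,
    )
    if variant is Variant.CA:
        kw.update(f=1.0, g=1.0)
    elif variant is Variant.DP:
        kw.update(K_A=0.0, g=1.0)
    elif variant is Variant.NC:
        kw.update(K_A=0.0, f=1.0)
    return ModelParams(**kw)
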