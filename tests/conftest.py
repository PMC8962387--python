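import numpy as np
import pytest

from perfcell.phantom import (
    AcquisitionParams,
    CellPlacementSpec,
    gamma_variate_aif,
    generate_phantom,
    simulate_dynamic_series,
    simulate_swi_pair,
)


@pytest.fixture(scope="session")
def small_phantom():
    return generate_phantom((16, 16, 8), seed=5)


@pytest.fixture(scope="session")
def noiseless_acq():
    return AcquisitionParams(n_frames=80, noise_sd=0.0)


@pytest.fixture(scope="session")
def noiseless_bundle(small_phantom, noiseless_acq):
    """Phantom + AIF + noiseless dynamic series, shared across tests."""
    aif = gamma_variate_aif(noiseless_acq)
    series = simulate_dynamic_series(small_phantom, aif, noiseless_acq, seed=3)
    return {"phantom": small_phantom, "aif": aif, "acq": noiseless_acq, "series": series}


@pytest.fixture(scope="session")
def swi_bundle():
    """Phantom + simulated SWI pair at default coupling, modest size."""
    phantom = generate_phantom((24, 24, 8), seed=9)
    spec = CellPlacementSpec(n_cells=600, coupling=0.6, seed=4)
    pre, post, true_mask = simulate_swi_pair(phantom, spec, (48, 48, 16))
    return {
        "phantom": phantom,
        "spec": spec,
        "pre": pre,
        "post": post,
        "true_mask": true_mask,
        "factors": (2, 2, 2),
    }


def upsample_mask(mask: np.ndarray, factors) -> np.ndarray:
    out = mask
    for ax, f in enumerate(factors):
        out = np.repeat(out, f, axis=ax)
    return out
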