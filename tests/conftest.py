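import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def warm_kernels():
    """Compile the numba kernels once with a desk-scale smoke run."""
    import cartsim

    cfg = cartsim.desk_config(n_cells=500, box_um=300.0, days=3.0, seed=0)
    return cartsim.run(cfg)


@pytest.fixture(scope="session")
def smoke_antigen_run(warm_kernels):
    """Short antigen-specific treated run (high dose, small organoid)."""
    import cartsim

    cfg = cartsim.desk_config(
        n_cells=200, box_um=300.0, days=3.0, seed=11, dose_ratio=2.0
    )
    return cartsim.run(cfg)


@pytest.fixture(scope="session")
def smoke_multi_run(warm_kernels):
    """Same scenario with multi-antigen (syn-Notch-like) recognition."""
    import cartsim
    from cartsim import MULTI_ANTIGEN, TCellParams

    cfg = cartsim.desk_config(
        n_cells=200, box_um=300.0, days=3.0, seed=11, dose_ratio=2.0,
    ).replace(tcell=TCellParams(recognition_mode=MULTI_ANTIGEN))
    return cartsim.run(cfg)
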