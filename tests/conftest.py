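import pytest

from gammamux import network as nw
from gammamux import stimulus as st


@pytest.fixture(scope="session")
def desk_bank():
    return st.build_gabor_bank(grid=32, n_scales=2, response_exponent=0.7)


@pytest.fixture(scope="session")
def desk_spec():
    return nw.build_quadrant_network(grid=32, n_scales=2)


@pytest.fixture(scope="session")
def desk_real(desk_spec):
    return nw.realize(desk_spec)


@pytest.fixture(scope="session")
def desk_drive(desk_bank):
    img = st.make_quadrant_stimulus([st.ObjectSpec("top-left", 1.0)], grid=32)
    return st.compute_drive(img, desk_bank)
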