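import numpy as np
import pytest

from mlcqa.geometry import MlcGeometry, hd120
from mlcqa.plan_fluence import Beam, ControlPoint


@pytest.fixture(scope="session")
def geometry() -> MlcGeometry:
    return hd120()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20240614)


def make_rectangle_beam(
    geometry: MlcGeometry,
    half_width: float = 10.0,
    n_open_pairs: int = 8,
    weights=(0.0, 1.0),
    beam_mu: float = 100.0,
) -> Beam:
    """Static rectangular aperture over the central quarter leaves."""
    first = geometry.n_pairs // 2 - n_open_pairs // 2
    cps = []
    for k, w in enumerate(weights):
        bank_a = np.zeros(geometry.n_pairs)
        bank_b = np.zeros(geometry.n_pairs)
        bank_a[first : first + n_open_pairs] = half_width
        bank_b[first : first + n_open_pairs] = -half_width
        cps.append(
            ControlPoint(
                index=k,
                bank_a=bank_a,
                bank_b=bank_b,
                cumulative_meterset_weight=float(w),
                jaw_x1=-50.0,
                jaw_x2=50.0,
                jaw_y1=-60.0,
                jaw_y2=60.0,
            )
        )
    return Beam(beam_id="rect", beam_mu=beam_mu, control_points=cps)


@pytest.fixture()
def rectangle_beam(geometry) -> Beam:
    return make_rectangle_beam(geometry)
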