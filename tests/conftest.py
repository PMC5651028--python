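import numpy as np
import pytest

from motormap import ArrayGeometry, IntensityGrid, VirtualSubject


def make_uniform_subject(theta: float, spread: float = 0.0, seed: int = 0) -> VirtualSubject:
    """Subject whose 32 electrodes all share the same true threshold."""
    geometry = ArrayGeometry()
    return VirtualSubject(
        geometry=geometry,
        thetas_pct=np.full(geometry.n_electrodes, float(theta)),
        hotspot_xy=(2.45, 1.05),
        theta_hot=float(theta),
        gradient_pct_per_mm=0.0,
        spread_pct=spread,
        predetermined_amplitude_uv=50.0,
        seed=seed,
        grid=IntensityGrid(),
    )


@pytest.fixture
def uniform_subject_factory():
    return make_uniform_subject
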