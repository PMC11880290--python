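from __future__ import annotations

import numpy as np
import pytest

from drfparams.contour_extraction import Contour, ContourConfig
from drfparams.phantom import PhantomSpec, generate_phantom
from drfparams.pipeline import PipelineConfig, run_case


@pytest.fixture(scope="session")
def default_spec() -> PhantomSpec:
    return PhantomSpec(RA_true=22.0, RL_true=11.0, UV_true=-2.0, PT_true=11.0,
                       displacement="volar", seed=3)


@pytest.fixture(scope="session")
def default_phantom(default_spec):
    """(ap_mask, lat_mask, truth) for a mid-range noiseless case."""
    return generate_phantom(default_spec)


@pytest.fixture(scope="session")
def default_result(default_phantom):
    ap, lat, _ = default_phantom
    result = run_case(ap, lat, PipelineConfig())
    assert result.error is None, result.error
    return result


@pytest.fixture
def contour_cfg() -> ContourConfig:
    return ContourConfig()


def square_contour(side: float = 20.0, origin=(0.0, 0.0)) -> Contour:
    x0, y0 = origin
    ring = np.array([
        [x0, y0], [x0 + side, y0], [x0 + side, y0 + side], [x0, y0 + side],
    ])
    return Contour(vertices=ring)


def circle_contour(radius: float = 50.0, center=(0.0, 0.0), n: int = 720) -> Contour:
    t = np.linspace(0, 2 * np.pi, n, endpoint=False)
    ring = np.column_stack([center[0] + radius * np.cos(t),
                            center[1] + radius * np.sin(t)])
    return Contour(vertices=ring)
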