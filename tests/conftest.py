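import math

import numpy as np
import pytest

from nucshape.config import PipelineConfig
from nucshape.contour import Contour


@pytest.fixture
def cfg() -> PipelineConfig:
    return PipelineConfig()


def circle_contour(radius: float, n: int = 720, center=(0.0, 0.0),
                   phase: float = 0.0) -> Contour:
    theta = np.linspace(0.0, 2.0 * math.pi, n, endpoint=False) + phase
    return Contour(np.column_stack([center[0] + radius * np.cos(theta),
                                    center[1] + radius * np.sin(theta)]))


def ellipse_contour(a: float, b: float, n: int = 720, rotation: float = 0.0) -> Contour:
    theta = np.linspace(0.0, 2.0 * math.pi, n, endpoint=False)
    x = a * np.cos(theta)
    y = b * np.sin(theta)
    if rotation:
        c, s = math.cos(rotation), math.sin(rotation)
        x, y = c * x - s * y, s * x + c * y
    return Contour(np.column_stack([x, y]))


def flower_contour(radius: float, amplitude: float, k: int, n: int = 2000) -> Contour:
    """k-lobed polar flower r(θ) = R (1 + a cos kθ)."""
    theta = np.linspace(0.0, 2.0 * math.pi, n, endpoint=False)
    r = radius * (1.0 + amplitude * np.cos(k * theta))
    return Contour(np.column_stack([r * np.cos(theta), r * np.sin(theta)]))
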