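import numpy as np
import pytest

from capstab import SceneSpec, render_sequence


@pytest.fixture(scope="session")
def small_scene() -> SceneSpec:
    """A small but feature-rich synthetic capillary scene for fast tests."""
    return SceneSpec(width=320, height=240, n_vessels=8, n_rbc=6, seed=7)


@pytest.fixture(scope="session")
def small_frames(small_scene):
    return render_sequence(small_scene, 8)


def random_similarity(rng: np.random.Generator):
    """Random transform over the documented parameter domain."""
    from capstab import SimilarityTransform

    return SimilarityTransform(
        s=rng.uniform(0.5, 2.0),
        theta=rng.uniform(-np.pi / 2, np.pi / 2),
        dx=rng.uniform(-20, 20),
        dy=rng.uniform(-20, 20),
    )


def homogeneous(t) -> np.ndarray:
    """3x3 homogeneous oracle matrix, built by direct scalar evaluation."""
    import math

    c, s = math.cos(t.theta), math.sin(t.theta)
    return np.array(
        [
            [t.s * c, -t.s * s, t.dx],
            [t.s * s, t.s * c, t.dy],
            [0.0, 0.0, 1.0],
        ]
    )
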