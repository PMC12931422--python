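import numpy as np
import pytest

import marrowdose as md
from marrowdose.synthetic import skeleton_centroid


@pytest.fixture(scope="session")
def mini_phantom() -> md.Phantom:
    """The default six-site miniature phantom."""
    return md.make_phantom()


@pytest.fixture(scope="session")
def mini_skeleton(mini_phantom) -> md.SkeletonPointSet:
    return md.phantom_skeleton_points(mini_phantom)


@pytest.fixture(scope="session")
def mini_centroid(mini_phantom) -> np.ndarray:
    return skeleton_centroid(mini_phantom)


def random_rigid(rng: np.random.Generator, center: np.ndarray,
                 max_angle_deg: float = 45.0, max_shift_mm: float = 100.0) -> md.RigidTransform:
    """A random rigid transform anchored at ``center`` (seeded by the caller)."""
    from marrowdose.synthetic import rotation_about_axis

    axis = rng.normal(size=3)
    angle = np.deg2rad(rng.uniform(0.0, max_angle_deg))
    shift = rng.uniform(-max_shift_mm, max_shift_mm, size=3)
    return md.RigidTransform.about_point(rotation_about_axis(axis, angle), shift, center)


def rms(a: np.ndarray, b: np.ndarray) -> float:
    d = np.asarray(a) - np.asarray(b)
    return float(np.sqrt((d**2).sum(axis=1).mean()))
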