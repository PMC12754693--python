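"""Shared fixtures: small synthetic cohorts and template geometry.

Everything is generated programmatically at test time; session scope keeps
the heavier cohort constructions to a single build.
"""

import numpy as np
import pytest

from footssm.correspondence import (
    extract_particles,
    generalized_procrustes,
    per_bone_local_frames,
)
from footssm.mesh import mirror_foot
from footssm.synthetic import GeneratorParams, build_parametric_foot, sample_cohort


@pytest.fixture(scope="session")
def tetrahedron():
    vertices = np.array(
        [[0.0, 0.0, 0.0], [10.0, 0.0, 0.0], [0.0, 10.0, 0.0], [0.0, 0.0, 10.0]]
    )
    faces = np.array([[0, 2, 1], [0, 1, 3], [0, 3, 2], [1, 2, 3]])
    return vertices, faces


@pytest.fixture(scope="session")
def rectus_foot():
    """One noiseless right foot at the rectus group means."""
    return build_parametric_foot(0.2, 9.8, 19.0, 1.0, "right", 0.0, seed=11)


@pytest.fixture(scope="session")
def small_params():
    """Down-scaled study conditions: same angle distributions, 8/8/8 feet."""
    return GeneratorParams(group_sizes=(8, 8, 8), seed=5)


@pytest.fixture(scope="session")
def small_cohort(small_params):
    return sample_cohort(small_params)


@pytest.fixture(scope="session")
def small_systems(small_cohort):
    """Particle systems of the small cohort with world and local frames."""
    feet = [mirror_foot(f) if f.side == "left" else f for f in small_cohort]
    systems = [extract_particles(f, 16) for f in feet]
    systems, _ = generalized_procrustes(systems, with_scaling=True)
    return per_bone_local_frames(systems)
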