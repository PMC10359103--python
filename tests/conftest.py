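import numpy as np
import pytest

from semgiz.motor_unit import GeometrySet, MuscleFiber, PopulationModel
from semgiz.source_model import ActionPotentialShape


@pytest.fixture
def shape():
    return ActionPotentialShape()


@pytest.fixture
def pop():
    return PopulationModel()


@pytest.fixture
def symmetric_fiber():
    """A 15 cm fiber innervated at its center, conduction 4 m/s."""
    return MuscleFiber(
        ref_point=(-0.075, 0.0, 0.0),
        alpha=0.0,
        beta=0.0,
        length=0.15,
        innervation_coord=0.075,
        cv=4.0,
    )


@pytest.fixture
def geometry():
    return GeometrySet()


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def dbscan_oracle(points, eps, min_samples):
    """Exhaustive density-reachability DBSCAN for tiny point sets.

    Independent of scikit-learn: neighborhoods by brute-force distances,
    clusters grown by explicit density reachability from core points.
    """
    n = len(points)
    d = np.linalg.norm(points[:, None, :] - points[None, :, :], axis=-1)
    neighbors = [np.flatnonzero(d[i] <= eps) for i in range(n)]
    core = [len(nb) >= min_samples for nb in neighbors]
    labels = np.full(n, -1)
    cluster = 0
    for i in range(n):
        if labels[i] != -1 or not core[i]:
            continue
        stack = [i]
        labels[i] = cluster
        while stack:
            j = stack.pop()
            if not core[j]:
                continue
            for k in neighbors[j]:
                if labels[k] == -1:
                    labels[k] = cluster
                    if core[k]:
                        stack.append(k)
        cluster += 1
    return labels
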