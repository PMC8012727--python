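import numpy as np
import pytest

from ctscore.geometry import CentroidSet, VelocityArrow


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_arrows(rng, n, clusters, view_id="view_0x1", box=10.0):
    """Random non-degenerate arrows labelled round-robin over clusters."""
    arrows = []
    for i in range(n):
        start = rng.uniform(-box, box, 2)
        end = start + rng.uniform(0.1, 1.0) * _unit(rng)
        arrows.append(
            VelocityArrow(
                view_id=view_id,
                start=tuple(start),
                end=tuple(end),
                start_cluster=clusters[i % len(clusters)],
                n_cells=int(rng.integers(1, 5)),
            )
        )
    return arrows


def random_centroids(rng, clusters, view_id="view_0x1", box=10.0):
    return CentroidSet(
        view_id=view_id,
        centroids={c: tuple(rng.uniform(-box, box, 2)) for c in clusters},
    )


def _unit(rng):
    theta = rng.uniform(0, 2 * np.pi)
    return np.array([np.cos(theta), np.sin(theta)])
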