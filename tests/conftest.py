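import numpy as np
import pytest

from skelprune import synthetic
from skelprune.cloud import PointCloud
from skelprune.skeleton import Skeleton


@pytest.fixture(scope="session")
def default_tree():
    return synthetic.generate_tree(seed=1)


@pytest.fixture(scope="session")
def default_sample(default_tree):
    return synthetic.sample_cloud(default_tree, seed=1)


@pytest.fixture(scope="session")
def two_view(default_sample):
    return synthetic.make_two_views(default_sample, noise_sigma=0.15, seed=1)


@pytest.fixture(scope="session")
def colonized(default_sample):
    """Default-parameter skeleton of the default synthetic tree."""
    from skelprune import colonize, preprocess

    inliers, _ = preprocess.remove_outliers(default_sample.cloud)
    return colonize.colonize(inliers)


def straight_branch_skeleton(step=10.0, n=10, tilt=None):
    """A vertical 3-node trunk followed by a straight branch of n edges."""
    sk = Skeleton()
    a = sk.add_node([0, 0, 0])
    b = sk.add_node([0, 0, 10], parent=a)
    c = sk.add_node([0, 0, 20], parent=b)
    d = tilt if tilt is not None else np.array([1.0, 0.0, 0.3])
    d = d / np.linalg.norm(d)
    cur = c
    pos = np.array([0.0, 0.0, 20.0])
    for _ in range(n):
        pos = pos + step * d
        cur = sk.add_node(pos, parent=cur)
    return sk


def random_tree_skeleton(rng, n_nodes=20, step=8.0):
    """Random rooted tree with geometric positions for graph-oracle tests."""
    sk = Skeleton()
    sk.add_node(rng.normal(0, 1, 3) + [0, 0, 0])
    for i in range(1, n_nodes):
        parent = int(rng.integers(0, i))
        direction = rng.normal(0, 1, 3)
        direction[2] = abs(direction[2]) + 0.2  # grow generally upward
        direction /= np.linalg.norm(direction)
        pos = sk.position(parent) + step * direction * rng.uniform(0.5, 1.5)
        sk.add_node(pos, parent=parent)
    return sk


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
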