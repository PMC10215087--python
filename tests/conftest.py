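import numpy as np
import pytest

from rkseg import ArchitectureConfig, SyntheticSpec, generate
from rkseg.synth import split

# the six variants at the smallest valid depths (I/R need s = d/2 >= 2)
SIX_VARIANTS = [
    ArchitectureConfig(orientation=o, backbone=b,
                       depth=(3 if b == "E" else 4),
                       width=4, in_channels=1, num_classes=2)
    for o in ("L", "R") for b in ("E", "I", "R")
]


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def tiny_dataset():
    """16 small two-class cases for smoke training."""
    spec = SyntheticSpec(n_cases=16, image_size=(32, 32), seed=7)
    return generate(spec)


@pytest.fixture(scope="session")
def small_split():
    spec = SyntheticSpec(n_cases=24, image_size=(32, 32), seed=3)
    return split(generate(spec), 6)


def extract_node_params(node):
    """Pull the weight arrays of a StageSubnetwork into plain dict form."""
    return {
        "w1": node.block1.conv.weight.data, "b1": node.block1.conv.bias.data,
        "g1": node.block1.norm.gamma.data, "be1": node.block1.norm.beta.data,
        "w2": node.block2.conv.weight.data, "b2": node.block2.conv.bias.data,
        "g2": node.block2.norm.gamma.data, "be2": node.block2.norm.beta.data,
    }


def extract_post_params(post):
    p = {
        "w1": post.block1.conv.weight.data, "b1": post.block1.conv.bias.data,
        "g1": post.block1.norm.gamma.data, "be1": post.block1.norm.beta.data,
        "w2": post.block2.conv.weight.data, "b2": post.block2.conv.bias.data,
        "g2": post.block2.norm.gamma.data, "be2": post.block2.norm.beta.data,
    }
    p["wc"] = post.classifier.weight.data
    p["bc"] = post.classifier.bias.data
    return p
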