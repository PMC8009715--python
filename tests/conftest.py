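"""Shared fixtures: seeded images and a tabular end-to-end pipeline runner."""

import numpy as np
import pytest

import mammotex as mx
import mammotex.network as nn


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_image(rng):
    """A seeded 64x64 8-bit noise image."""
    return mx.GrayImage.from_array(rng.integers(0, 256, (64, 64)).astype(np.uint8))


@pytest.fixture
def textured_image():
    """A deterministic smooth texture (distinct from pure noise)."""
    m = mx.make_texture_dataset(
        specs=(mx.TextureClassSpec(1, 2.0, 40, 120, 1),), size=64, seed=7
    )
    return mx.GrayImage.from_array(m.images[0])


def run_tabular_pipeline(class_sep: float, seed: int, balance: bool,
                         max_epochs: int = 15):
    """Full tabular pipeline: (oversample) -> ReliefF top-10 -> LM net.

    Returns (test accuracy, mean minority-class recall) on the held-out
    test split, with the class structure of the published 411-image
    distribution (majority class = label 2).
    """
    ds = mx.make_tabular_dataset(class_sep=class_sep, seed=100 + seed)
    table = mx.oversample(ds, mx.AdasynConfig(seed=seed)) if balance else ds
    weights = mx.relieff_weights(table.X, table.y, mx.ReliefFConfig())
    top = mx.select_top(weights, 10)
    sel = mx.LabeledDataset(table.X[:, top], table.y)
    net = nn.train(
        nn.init(mx.NetworkSpec(n_inputs=10, seed=seed)),
        sel,
        mx.TrainConfig(max_epochs=max_epochs, seed=seed),
    )
    te = net.split_indices["test"]
    cm = mx.confusion(sel.y[te], nn.predict(net, sel.X[te]), labels=np.arange(1, 9))
    accuracy = np.trace(cm.counts) / cm.total
    minority_recall = float(
        np.mean(
            [mx.sensitivity(mx.per_class_counts(cm, l)) for l in range(1, 9) if l != 2]
        )
    )
    return accuracy, minority_recall
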