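import numpy as np
import pytest

from noisyvision import network, synthetic, training


@pytest.fixture(scope="session")
def shape_dataset():
    """Experiment-scale synthetic dataset: 6 categories, 50 train / 25 test each.

    Six categories keep the discrimination fine-grained enough that a
    clean-trained network stays in the noise-susceptible regime the layer
    analyses probe; with fewer, easier categories even a standard network's
    deep layers are noise robust.
    """
    return synthetic.generate_image_dataset(6, 50, 25, canvas=64, seed=11)


@pytest.fixture(scope="session")
def tiny_dataset():
    return synthetic.generate_image_dataset(4, 30, 8, canvas=32, seed=7)


@pytest.fixture(scope="session")
def tiny_model(tiny_dataset):
    """A small quickly trained network on a 32-pixel canvas for unit tests."""
    im, lab, _ = tiny_dataset.subset("train")
    m = network.SmallCNN(canvas=32, n_classes=4, channels=(8, 16), fc_units=32, seed=0)
    m, _ = training.train_model(m, im, lab, cfg=training.TrainConfig(epochs=25, seed=0))
    return m


@pytest.fixture(scope="session")
def trained_models(shape_dataset):
    """The four training conditions of the noise-training protocol.

    clean      noise-free images only;
    noise      equal-proportion mix of clean images and Gaussian-noise images
               at SSNR levels drawn uniformly from 0.2-0.99;
    low_only   Gaussian-noise images at SSNR 0.2 only;
    mixed02    equal mix of clean images and SSNR-0.2 Gaussian-noise images.

    All four receive the same number of epochs from the same initialisation
    (a 30-epoch from-scratch schedule; the paper-protocol 20 epochs presume a
    pretrained starting point).
    """
    tr_im, tr_lab, _ = shape_dataset.subset("train")
    mixes = {
        "clean": training.CLEAN_MIX,
        "noise": training.NoiseMixSpec(
            [
                training.MixComponent("clean", None, 0.5),
                training.MixComponent("gaussian", (0.2, 0.99), 0.5),
            ]
        ),
        "low_only": training.NoiseMixSpec([training.MixComponent("gaussian", 0.2, 1.0)]),
        "mixed02": training.NoiseMixSpec(
            [
                training.MixComponent("clean", None, 0.5),
                training.MixComponent("gaussian", 0.2, 0.5),
            ]
        ),
    }
    models = {}
    for name, mix in mixes.items():
        m = network.SmallCNN(canvas=64, n_classes=6, seed=0)
        m, log = training.train_model(m, tr_im, tr_lab, mix=mix, cfg=training.TrainConfig(epochs=30, seed=0))
        models[name] = (m, log)
    return models
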