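import numpy as np
import pytest

from deepcenterline import geometry, network, simulator, synthvideo

K_SMALL = 25  # point count used by the fast test fixtures


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def basis():
    """PCA shape basis fitted on simulated postures (k=25)."""
    shapes = simulator.shape_ensemble(np.random.default_rng(42), 800, K_SMALL)
    return geometry.fit_pca_basis(shapes)


@pytest.fixture(scope="session")
def shape_samples():
    """Held-out simulated postures, independent of the basis ensemble."""
    return simulator.shape_ensemble(np.random.default_rng(43), 60, K_SMALL)


@pytest.fixture(scope="session")
def tiny_model(basis):
    """Small untrained detector+encoder for architecture/loss tests."""
    cfg = network.NetworkConfig(
        C=4, kappa=basis.kappa, D=4, channels=(8, 16, 16, 32),
        stem_channels=8, stem_ksize=5, head_width=64, encoder_width=32,
        sigma_l=50.0)
    return network.CenterlineModel(cfg, basis, seed=3)


@pytest.fixture(scope="session")
def tiny_batch():
    """One small labeled synthetic batch (2 clips, 64×64, 1–3 worms)."""
    cfg = synthvideo.BatchConfig(H=64, W=64, k=K_SMALL, n_worms_range=(1, 3))
    return synthvideo.make_training_batch(np.random.default_rng(5), 2, cfg)


def random_triplet(rng, k=K_SMALL, scale=10.0):
    base = np.cumsum(rng.normal(size=(k, 2)), axis=0) * scale / np.sqrt(k)
    return np.stack([base + rng.normal(size=(k, 2)),
                     base,
                     base - rng.normal(size=(k, 2))])
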