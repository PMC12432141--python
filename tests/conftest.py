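import numpy as np
import pytest

from caescreen.cae import CAEConfig, build_cae
from caescreen.preprocess import preprocess
from caescreen.synthetic import (ARTIFACT_KINDS, SceneSpec, default_artifact,
                                 generate_artifact_image, generate_clean_image)

# Small raw scenes (128 px -> 64 px model input) keep the fixture model
# trainable in seconds while preserving the full pipeline geometry.
SMALL_SIDE = 128


@pytest.fixture(scope="session")
def small_spec():
    return SceneSpec(side=SMALL_SIDE, n_signals=8)


@pytest.fixture(scope="session")
def small_clean_images(small_spec):
    return [generate_clean_image(small_spec.replace(seed=s)) for s in range(48)]


@pytest.fixture(scope="session")
def small_artifact_images(small_spec):
    out = []
    for j in range(12):
        kind = ARTIFACT_KINDS[j % len(ARTIFACT_KINDS)]
        spec = small_spec.replace(seed=1000 + j,
                                  artifact=default_artifact(kind, SMALL_SIDE))
        out.append(generate_artifact_image(spec))
    return out


@pytest.fixture(scope="session")
def small_clean_pre(small_clean_images):
    return np.asarray([preprocess(im.image) for im in small_clean_images],
                      dtype=np.float32)


@pytest.fixture(scope="session")
def small_artifact_pre(small_artifact_images):
    return np.asarray([preprocess(im.image) for im in small_artifact_images],
                      dtype=np.float32)


@pytest.fixture(scope="session")
def trained_small(small_clean_pre, small_artifact_pre):
    """A small autoencoder trained on 40 clean synthetic images."""
    cfg = CAEConfig(input_side=SMALL_SIDE // 2, filters=(8, 16), epochs=6, seed=3)
    model = build_cae(cfg)
    model.train(small_clean_pre[:40], clean_val=small_clean_pre[40:],
                artifact_val=small_artifact_pre)
    return model
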