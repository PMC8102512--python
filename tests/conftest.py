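import numpy as np
import pytest

from funduscam import models, pipeline, synthetic


@pytest.fixture(scope="session")
def small_spec() -> synthetic.SceneSpec:
    return synthetic.SceneSpec(image_size=64)


@pytest.fixture(scope="session")
def graded_item(small_spec) -> synthetic.AnnotatedFundus:
    """One moderate-grade image with all pathology components present."""
    return synthetic.generate_image(synthetic.spec_for_grade(small_spec, 3), seed=7)


def quadrant_dataset(n_per_class: int = 24, size: int = 16, seed: int = 0):
    """Images whose class (0-4) is encoded only in the brightness of the
    top-left quadrant; everything else is i.i.d. noise."""
    rng = np.random.default_rng(seed)
    xs, ys = [], []
    for cls in range(5):
        for _ in range(n_per_class):
            img = rng.uniform(0.1, 0.3, size=(size, size, 3))
            img[: size // 2, : size // 2] += 0.12 + 0.14 * cls
            xs.append(np.clip(img, 0, 1))
            ys.append(cls)
    order = rng.permutation(len(xs))
    return np.stack(xs)[order], np.array(ys)[order]


@pytest.fixture(scope="session")
def quadrant_model():
    """A model trained until the quadrant-brightness task is solved."""
    x, y = quadrant_dataset()
    model = models.build_model(
        models.ModelConfig(variant="plain", input_size=16, base_channels=8, seed=1))
    history = models.train(
        model, x[:100], y[:100], x[100:], y[100:],
        models.TrainConfig(head_epochs=2, full_epochs=60, patience=60,
                           learning_rate=0.01, seed=0))
    return model, history, (x, y)


@pytest.fixture(scope="session")
def smoke_run(tmp_path_factory):
    """A reduced but complete end-to-end pipeline run shared across tests."""
    out_dir = tmp_path_factory.mktemp("smoke_run")
    config = pipeline.RunConfig(
        scene=synthetic.SceneSpec(image_size=32),
        n_per_grade=8,
        rebalance_cap=8,
        variants=("separable", "plain"),
        train=models.TrainConfig(head_epochs=1, full_epochs=2, patience=2,
                                 learning_rate=0.003, seed=0),
        base_channels=4,
        seed=11,
    )
    summary = pipeline.run(config, out_dir)
    return config, out_dir, summary
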