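import numpy as np
import pytest
import yaml
from hypothesis import settings

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")

from xrfseed.classifier import evaluate_and_select, split_dataset, train_models
from xrfseed.io import save_element_stack, save_rgb
from xrfseed.synth import generate_layout, generate_pixel_dataset, pixel_table_from_layout


@pytest.fixture(scope="session")
def default_layout():
    """The standard synthetic fixture: 2 rows x 3 accessions x 5 seeds,
    3 adherent pairs, noiseless element maps."""
    return generate_layout()


@pytest.fixture(scope="session")
def separable_models():
    """Four classifiers trained on highly separable synthetic pixel data."""
    table = generate_pixel_dataset(n_records=1000, separability=10.0, rng_seed=0)
    train, test = split_dataset(table, 0.8, rng_seed=0)
    models = train_models(train, rng_seed=0)
    report = evaluate_and_select(models, test, n_train=len(train), rng_seed=0)
    return models, report, test


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def pipeline_inputs(tmp_path_factory, default_layout):
    """The default fixture's files plus a minimal pipeline config on disk."""
    out = tmp_path_factory.mktemp("pipeline_inputs")
    rgb, stack, gt = default_layout
    save_rgb(out / "rgb.png", rgb)
    manifest = save_element_stack(out / "elements", stack)
    pixel_table_from_layout(rgb, gt, rng_seed=0).to_frame().to_csv(
        out / "pixels.csv", index=False
    )
    cfg = {
        "rgb": "rgb.png",
        "elements_dir": "elements",
        "element_manifest": manifest,
        "pixel_table": "pixels.csv",
        "n_rows": 2,
        "rng_seed": 0,
    }
    (out / "config.yaml").write_text(yaml.safe_dump(cfg))
    return out, gt, stack
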