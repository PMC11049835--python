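import numpy as np
import pytest

from spermfish.metrics import measure_dataset
from spermfish.synthetic import (
    RenderConfig,
    StudyDesign,
    default_presets,
    generate_dataset,
    render_cell_image,
    sample_cell_truth,
)

STUDY_SEED = 11


@pytest.fixture(scope="session")
def presets():
    return default_presets()


@pytest.fixture(scope="session")
def rendered_study(presets):
    """Full default study (5 subjects x 50 cells), rendered and measured.

    Returns (truth_table, measurements, merged) where merged joins the
    per-cell measurements with the generator ground truth.
    """
    design = StudyDesign(seed=STUDY_SEED)
    images, truth, _ = generate_dataset(design, presets)
    measurements = measure_dataset(images, truth[["cell_id", "subject_id", "class"]])
    merged = measurements.merge(truth[["cell_id", "true_itd", "true_cta"]], on="cell_id")
    return truth, measurements, merged


@pytest.fixture()
def clean_cell(presets):
    """One noiseless rendered cell with point-mass metrics (itd=0.5, cta=0.25)."""
    rng = np.random.default_rng(5)
    truth = sample_cell_truth(presets["low"], rng, cell_id="clean", itd=0.5, cta=0.25)
    img = render_cell_image(truth, RenderConfig(noise_scale=0.0), np.random.default_rng(6))
    return truth, img
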