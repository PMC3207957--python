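import numpy as np
import pytest

from cardiot1.geometry import LVMask, aha17_labels
from cardiot1.phantom import PhantomSpec, make_heart_phantom


@pytest.fixture(scope="session")
def default_spec():
    return PhantomSpec()


@pytest.fixture(scope="session")
def default_truth(default_spec):
    return make_heart_phantom(default_spec)


@pytest.fixture(scope="session")
def ed_mask(default_truth):
    return LVMask(
        labels=default_truth.mask_ed,
        phase="ED",
        spacing_mm=default_truth.spacing_mm,
        rv_insertion_angle_deg=default_truth.rv_insertion_angle_deg,
    )


@pytest.fixture(scope="session")
def es_mask(default_truth):
    return LVMask(
        labels=default_truth.mask_es,
        phase="ES",
        spacing_mm=default_truth.spacing_mm,
        rv_insertion_angle_deg=default_truth.rv_insertion_angle_deg,
    )


@pytest.fixture(scope="session")
def segmentation(ed_mask):
    return aha17_labels(ed_mask)


@pytest.fixture(scope="session")
def pipeline_run(tmp_path_factory):
    """One full default-phantom pipeline run shared by all tests that
    inspect end-to-end behaviour (it costs ~40 s)."""
    from cardiot1.pipeline import RunConfig, run_pipeline

    out = tmp_path_factory.mktemp("pipeline_run")
    config = RunConfig(out_dir=str(out), seed=11)
    manifest = run_pipeline(config)
    return config, manifest, out


def lesion_mask_3d(truth):
    """Boolean volume of the ground-truth lesion sector (helper)."""
    spec = truth.spec
    return np.isclose(truth.t1_pre_map, spec.t1_infarct_ms) & (truth.mask_ed == 2)
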