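import numpy as np
import pytest

from oatpquant import quantify, segment, simgen


def make_generator(**overrides) -> simgen.GeneratorConfig:
    """Small, fast generator config for unit tests (full-size configs are
    built explicitly where the test needs the study design)."""
    defaults = dict(
        image_shape=(128, 128),
        cohort_sizes={"gbm": 3, "control": 3},
        vessel_params={"count": 2, "width_px": 8, "tortuosity": 0.25, "rim_px": 2},
        seed=0,
    )
    defaults.update(overrides)
    return simgen.GeneratorConfig(**defaults)


def noise_off(cfg: simgen.GeneratorConfig) -> simgen.GeneratorConfig:
    """Disable every stochastic intensity component: ideal imaging."""
    cfg.noise = {"background_level": 100.0, "gaussian_sd": 0.0, "poisson": False}
    cfg.blur_sigma = 0.0
    cfg.case_cv = 0.0
    cfg.object_cv = 0.0
    return cfg


def cohort_fold(cfg: simgen.GeneratorConfig, measure: str) -> quantify.FoldChange:
    """Run simulate -> segment -> quantify and return the group fold."""
    params = segment.SegmentationParams()
    summaries = []
    for case, _truth in simgen.iter_cohort(cfg):
        seg = segment.segment_case(case, params)
        summary, _objects = quantify.summarize_case([case], [seg])
        summaries.append(summary)
    table = quantify.cohort_table(summaries)
    return quantify.group_fold_change(table, measure)


@pytest.fixture(scope="session")
def default_case():
    """One default-noise GBM case with ground truth (shared, read-only)."""
    cfg = simgen.GeneratorConfig(image_shape=(256, 256), seed=0)
    return simgen.generate_case_image(cfg, "gbm", 123, case_id="shared_gbm")


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
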