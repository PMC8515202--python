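import numpy as np
import pytest

import hdprogression as h


@pytest.fixture(scope="session")
def gen_config():
    # study-scale cohort: 150 gene-positive subjects plus controls
    return h.GeneratorConfig(
        n_per_group={"HC": 100, "PreHD": 95, "HD": 55}, seed=42
    )


@pytest.fixture(scope="session")
def cohort_truths(gen_config):
    return h.generate_cohort(gen_config)


@pytest.fixture(scope="session")
def direction_map(gen_config):
    return {r.name: r.direction for r in gen_config.regions}


@pytest.fixture(scope="session")
def adjustment(cohort_truths):
    cohort, _ = cohort_truths
    return h.fit_adjustment(cohort)


@pytest.fixture(scope="session")
def adjusted(cohort_truths, adjustment, direction_map):
    cohort, _ = cohort_truths
    return h.apply_adjustment(cohort, adjustment, direction_map)


@pytest.fixture(scope="session")
def gene_positive(cohort_truths, adjusted):
    _, truths = cohort_truths
    return adjusted.subset([t.subject_id for t in truths if t.group != "HC"])


@pytest.fixture(scope="session")
def true_shifts(cohort_truths):
    _, truths = cohort_truths
    return {t.subject_id: t.time_shift for t in truths if t.group != "HC"}


@pytest.fixture(scope="session")
def model_config():
    return h.ModelConfig(seed=1)


@pytest.fixture(scope="session")
def fitted(gene_positive, model_config):
    return h.fit(gene_positive, model_config)


@pytest.fixture(scope="session")
def anchored(fitted, gene_positive):
    return h.anchor_timeline(fitted, h.hd_baseline_means(gene_positive))


@pytest.fixture(scope="session")
def gene_frame_offset(anchored, fitted, cohort_truths):
    """Additive offset mapping anchored user time to generator disease time."""
    _, truths = cohort_truths
    mbar = np.mean([t.time_shift for t in truths if t.group != "HC"])
    return anchored.origin - fitted.origin + mbar
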