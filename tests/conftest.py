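import numpy as np
import pytest

from satb2phenomics import (
    CohortSpec,
    FaceParams,
    load_gene_model,
    load_role_map,
    load_study_phenotypes,
    load_study_variants,
    load_template,
    render_face,
)


@pytest.fixture(scope="session")
def roles():
    return load_role_map()


@pytest.fixture(scope="session")
def template():
    return load_template()


@pytest.fixture(scope="session")
def gene():
    return load_gene_model()


@pytest.fixture(scope="session")
def study_variants():
    return load_study_variants()


@pytest.fixture(scope="session")
def study_phenotypes():
    return load_study_phenotypes()


@pytest.fixture(scope="session")
def symmetric_face():
    """Noiseless, perfectly symmetric rendered face."""
    return render_face(FaceParams(noise_sd=0.0), seed=1)


@pytest.fixture(scope="session")
def bumpy_face():
    """Noiseless face with symmetric random feature offsets."""
    offsets = np.random.default_rng(0).normal(0.0, 3.0, size=(36, 2))
    return render_face(FaceParams(subject_id="B", feature_offsets=offsets,
                                  noise_sd=0.0), seed=2)
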