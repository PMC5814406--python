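import pytest

from mitomirscan import (
    load_anchors,
    load_evidence,
    load_features,
    load_mirnas,
    load_reference,
    load_targets,
)


@pytest.fixture(scope="session")
def genome():
    return load_reference()


@pytest.fixture(scope="session")
def feature_map(genome):
    return load_features(genome=genome)


@pytest.fixture(scope="session")
def mirnas():
    return load_mirnas()


@pytest.fixture(scope="session")
def mirnas_by_id(mirnas):
    return {m.id: m for m in mirnas}


@pytest.fixture(scope="session")
def evidence():
    return load_evidence()


@pytest.fixture(scope="session")
def targets():
    return load_targets()


@pytest.fixture(scope="session")
def anchors():
    return load_anchors()
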