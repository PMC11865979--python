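"""Shared fixtures: canonical synthetic corpora (seed 7) reused across tests.

Session-scoped because corpus generation dominates test runtime; every test
treats the fixtures as read-only (the underlying arrays are frozen).
"""

import pytest

from chemfuse.synth import default_templates, generate_training_corpus

CANONICAL_SEED = 7
CONCENTRATIONS = (2.8, 5.7, 50.0, 500.0)


def _one_class_corpus(analyte: str):
    return generate_training_corpus(
        {analyte: default_templates()[analyte]},
        n_per_analyte=10,
        concentrations=CONCENTRATIONS,
        seed=CANONICAL_SEED,
    )


@pytest.fixture(scope="session")
def dmmp_corpus():
    return _one_class_corpus("dmmp")


@pytest.fixture(scope="session")
def acetone_corpus():
    return _one_class_corpus("acetone")


@pytest.fixture(scope="session")
def tatp_corpus():
    return _one_class_corpus("tatp")


@pytest.fixture(scope="session")
def mixed_corpus():
    """Small three-analyte corpus for multiclass/negative-control tests."""
    return generate_training_corpus(
        default_templates(),
        n_per_analyte=3,
        concentrations=(5.7, 50.0),
        seed=CANONICAL_SEED,
    )
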