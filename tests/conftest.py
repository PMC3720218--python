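"""Shared fixtures: synthetic corpora and their descriptor designs.

The session-scoped corpora define the simulation conditions used across
the model and acceptance tests: a 600-molecule surrogate corpus at the
default noise level sigma = 2 kcal/mol (about 4,800 unique bonds after
deduplication) for parameter recovery, and a 200-molecule corpus of
small (<= 30 atom) molecules for descriptor property checks.
"""

import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from bondscope.dataset import build_records, deduplicate, design_matrix
from bondscope.descriptors import build_catalog
from bondscope.models import RFConfig, train_rf
from bondscope.synthdata import (
    default_params,
    generate_corpus,
    generate_molecules,
    surrogate_bde,
)

SIGMA = 2.0

#: Forest configuration for the surrogate-recovery experiments: more
#: candidate variables per split than the sqrt default, because the
#: surrogate signal concentrates in a handful of sphere-0 columns.
RECOVERY_RF = dict(n_trees=300, max_features=0.5)


@pytest.fixture(scope="session")
def recovery_corpus():
    return generate_corpus(600, default_params(sigma=SIGMA), seed=11)


@pytest.fixture(scope="session")
def selection3_catalog():
    return build_catalog("selection3")


@pytest.fixture(scope="session")
def recovery_records(recovery_corpus, selection3_catalog):
    records = build_records(recovery_corpus, selection3_catalog)
    unique, _ = deduplicate(records)
    return unique


@pytest.fixture(scope="session")
def recovery_design(recovery_corpus, recovery_records):
    """(X, y_noisy, y_noiseless) for the deduplicated recovery records."""
    X, y = design_matrix(recovery_records)
    noiseless = default_params(sigma=0.0)
    label0 = {
        (entry.graph.title, entry.bond): surrogate_bde(
            entry.graph, entry.bond, noiseless
        )
        for entry in recovery_corpus
    }
    y0 = np.array([label0[(r.mol_id, r.bond)] for r in recovery_records])
    return X, y, y0


@pytest.fixture(scope="session")
def rf_recovery(recovery_design):
    X, y, _ = recovery_design
    return train_rf(
        X, y, RFConfig(seed=3, **RECOVERY_RF), compute_importance=False
    )


@pytest.fixture(scope="session")
def property_molecules():
    """200 random admissible molecules of at most ~30 atoms."""
    return generate_molecules(200, max_heavy_atoms=9, seed=23)


@pytest.fixture(scope="session")
def small_corpus():
    return generate_corpus(120, default_params(sigma=SIGMA), seed=5)
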