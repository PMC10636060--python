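"""Shared fixtures: small toy structures and oracle predictions.

Everything is generated programmatically and seeded; session scope keeps
the expensive objects (structures, predictions) shared across tests.
"""

import numpy as np
import pytest

from cgrna.evalio import pairs_to_matrix
from cgrna.features import Alignment
from cgrna.geometry import compute_geometries, discretize
from cgrna.synthetic import (OracleConfig, ToySpec, make_toy_structure,
                             oracle_prediction, synthetic_msa)


@pytest.fixture(scope="session")
def hairpin_spec():
    return ToySpec("GGGGGGAAAAACCCCCCAAGC", "((((((.....))))))....", seed=5)


@pytest.fixture(scope="session")
def hairpin(hairpin_spec):
    return make_toy_structure(hairpin_spec)


@pytest.fixture(scope="session")
def hairpin_ss(hairpin_spec):
    return pairs_to_matrix(hairpin_spec.pairs, len(hairpin_spec.sequence))


@pytest.fixture(scope="session")
def hairpin_labels(hairpin):
    return discretize(compute_geometries(hairpin))


@pytest.fixture(scope="session")
def sharp_oracle(hairpin):
    return oracle_prediction(
        hairpin, OracleConfig(sigma_dist=1.5, sigma_ang=18.0, seed=1))


@pytest.fixture(scope="session")
def two_stem_spec():
    return ToySpec("AGGGGAUAACCCCGGGGCUUUUCCCAA",
                   ".((((....)))).(((.....)))..", seed=7)


@pytest.fixture(scope="session")
def two_stem(two_stem_spec):
    return make_toy_structure(two_stem_spec)


@pytest.fixture(scope="session")
def small_msa(hairpin_spec):
    rows = synthetic_msa(hairpin_spec.sequence, hairpin_spec.dotbracket,
                         n=12, mutation_rate=0.25, seed=3)
    return Alignment(rows)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
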