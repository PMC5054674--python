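"""Shared fixtures: small synthetic cohorts and their pipeline products.

Spatial resolution and cohort sizes are reduced relative to the clinical
defaults so the suite stays fast; group structure (dilation, ejection
fractions, bend contrast) is unchanged.
"""

import numpy as np
import pytest

from lamorph.parallel_transport import (
    deformation_pca,
    grand_mean_of_series,
    linear_shift,
)
from lamorph.synthetic_data import CohortSpec, generate_cohort
from lamorph.temporal_homology import (
    pooled_observed_decomposition,
    reconstruct_homologous_series,
)


def small_spec(**overrides) -> CohortSpec:
    defaults = dict(n_control=8, n_case=8, rings=8, points_per_ring=8, seed=7)
    defaults.update(overrides)
    return CohortSpec(**defaults)


@pytest.fixture()
def rng():
    # fresh generator per test: deterministic and order-independent
    return np.random.default_rng(20161007)


@pytest.fixture(scope="session")
def tiny_cohort():
    """16 subjects, 8x8 ring grid, default group structure."""
    return generate_cohort(small_spec())


@pytest.fixture(scope="session")
def tiny_series(tiny_cohort):
    decomp = pooled_observed_decomposition(tiny_cohort)
    return [reconstruct_homologous_series(s, decomp) for s in tiny_cohort]


@pytest.fixture(scope="session")
def tiny_deformation(tiny_series):
    gm = grand_mean_of_series(tiny_series)
    transported = [linear_shift(s, gm) for s in tiny_series]
    return deformation_pca(transported)


def random_config(rng, k=30, scale=10.0):
    return scale * rng.standard_normal((k, 3))


def random_rotation(rng):
    q, _ = np.linalg.qr(rng.standard_normal((3, 3)))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    return q
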