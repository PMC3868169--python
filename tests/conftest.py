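"""Shared fixtures: synthetic cohorts at two scales.

The default-scale cohort (39 patients / 37 controls, T=170) is expensive, so
it is generated once per session together with its preprocessed matrices and
localization result and shared by every test that needs realistic study
conditions.
"""

from __future__ import annotations

import numpy as np
import pytest

from rcga import CohortSpec, generate_cohort, locate_sources, small_spec
from rcga.pipeline import cohort_matrices, preprocess_matrices


def link_pairs_of(spec: CohortSpec) -> list[tuple[str, str]]:
    return [(l.roi_a, l.roi_b) for l in spec.links]


@pytest.fixture(scope="session")
def default_cohort():
    """Default-scale effect cohort with preprocessing and localization."""
    spec = CohortSpec()
    cohort = generate_cohort(spec, seed=1)
    pre = preprocess_matrices(cohort_matrices(cohort), spec.tr)
    links = link_pairs_of(spec)
    coords = {
        roi: cohort.data[cohort.subject_ids[0]][roi].voxel_coords for roi in pre
    }
    located = locate_sources(
        pre, cohort.labels, links, coords=coords, affine=cohort.affine
    )
    return {
        "spec": spec,
        "cohort": cohort,
        "pre": pre,
        "links": links,
        "coords": coords,
        "located": located,
    }


@pytest.fixture(scope="session")
def small_cohort():
    """Fast cohort (4+4 subjects, T=96) for interface-level tests."""
    spec = small_spec()
    cohort = generate_cohort(spec, seed=3)
    pre = preprocess_matrices(cohort_matrices(cohort), spec.tr)
    return {
        "spec": spec,
        "cohort": cohort,
        "pre": pre,
        "links": link_pairs_of(spec),
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(20260923)
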