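"""Shared fixtures: small phantom specs, templates and a synthesized cohort.

Everything is generated programmatically at session scope so the suite needs
no bundled data files.
"""

from __future__ import annotations

import numpy as np
import pytest

from tbmpipe import phantom
from tbmpipe.core_image import Volume


@pytest.fixture(scope="session")
def spec36() -> phantom.PhantomSpec:
    """Small default-parameter phantom used by the fast tests."""
    return phantom.PhantomSpec(grid_shape=(36, 36, 36), seed=7)


@pytest.fixture(scope="session")
def template36(spec36):
    return phantom.build_template(spec36)


@pytest.fixture(scope="session")
def cohort_dir(tmp_path_factory, spec36):
    """A full (8, 10, 7) x two-modality cohort on disk."""
    out = tmp_path_factory.mktemp("cohort36")
    manifest = phantom.synthesize_cohort(spec36, out)
    return out, manifest


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


@pytest.fixture()
def random_volume(rng) -> Volume:
    aff = np.eye(4)
    aff[:3, :3] = np.diag([0.15, 0.15, 0.15])
    return Volume(rng.normal(10, 2, (16, 16, 16)), aff)
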