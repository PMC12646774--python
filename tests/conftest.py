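import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import eggsurf as es

settings.register_profile(
    "suite", deadline=None, derandomize=True, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow,
                           HealthCheck.function_scoped_fixture],
)
settings.load_profile("suite")


def make_map(values, valid=None, corrected=True, pitch=1.0):
    """Build a HeightMap from a 2-D array; invalid pixels via ``valid`` mask.

    ``corrected=True`` marks the map as form-corrected so compute_texture
    does not warn in tests that exercise the moment formulas directly.
    """
    values = np.asarray(values, dtype=float)
    if valid is None:
        valid = np.isfinite(values)
    meta = {"corrected": True} if corrected else {}
    return es.HeightMap(values, valid, pitch, pitch, meta)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_tree():
    """((A:1,B:1):1,C:2); — 3 ultrametric tips, depth 2."""
    import io as _io

    import dendropy

    return dendropy.Tree.get(data="((A:1,B:1):1,C:2);", schema="newick")


@pytest.fixture
def random_map(rng):
    h = rng.normal(0, 10, (30, 40))
    return make_map(h)
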