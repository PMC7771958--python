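"""Shared fixtures: phantom cohorts and pipeline runs reused across tests.

The default cohort (ten 64^3 subjects) and its leave-one-out runs are
session-scoped because atlas building is the expensive step; individual
tests only read from them.
"""

from __future__ import annotations

from types import SimpleNamespace

import numpy as np
import pytest

from massp.inference import parcellate
from massp.phantom import PhantomSpec, ShapeRecipe, default_spec, make_cohort
from massp.priors import build_atlas
from massp.workflows import RunConfig, leave_one_out

# structures >= 500 voxels in the default phantom (large) vs the rest
LARGE_STRUCTURES = (1, 2, 4, 6)
SMALL_STRUCTURES = (3, 5, 7)


def mini_phantom_spec(seed: int = 7) -> PhantomSpec:
    """A 3-ball 24^3 cohort spec: cheap enough for dense oracles."""
    recipes = (
        ShapeRecipe(1, "ball_a", "ball", (9, 12, 12), (4,), (0.75, 40.0, 0.02), (0.01, 1.0, 0.002)),
        ShapeRecipe(2, "ball_b", "ball", (16, 12, 12), (3,), (0.55, 60.0, 0.08), (0.01, 1.0, 0.002)),
        ShapeRecipe(3, "ball_c", "ball", (12, 18, 12), (2.5,), (0.90, 20.0, -0.01), (0.01, 1.0, 0.002)),
    )
    return PhantomSpec(
        grid_size=24,
        recipes=recipes,
        deform_amplitude_mm=0.8,
        deform_smoothness_mm=4.0,
        seed=seed,
    )


@pytest.fixture(scope="session")
def mini_cohort():
    return make_cohort(mini_phantom_spec(), 5)


@pytest.fixture(scope="session")
def mini_atlas(mini_cohort):
    return build_atlas(
        [s.truth for s in mini_cohort], [s.contrasts for s in mini_cohort]
    )


@pytest.fixture(scope="session")
def default_cohort():
    return make_cohort(default_spec(42), 10)


@pytest.fixture(scope="session")
def fold0(default_cohort):
    """Atlas from subjects 1..9, held-out parcellation of subject 0, with
    intermediates retained."""
    train = default_cohort[1:]
    atlas = build_atlas([s.truth for s in train], [s.contrasts for s in train])
    result = parcellate(atlas, default_cohort[0].contrasts, keep_intermediates=True)
    return SimpleNamespace(atlas=atlas, test=default_cohort[0], result=result)


@pytest.fixture(scope="session")
def loo_folds(default_cohort):
    return leave_one_out(default_cohort, RunConfig())


@pytest.fixture()
def rng():
    return np.random.default_rng(20260919)
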