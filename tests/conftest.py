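"""Shared fixtures: phantoms, rendered film studies and full pipeline runs.

The heavy end-to-end fixtures are session-scoped: three seeded synthetic
studies (the package's standard conditions) are reconstructed once and shared
by the pipeline, evaluation and acceptance tests.
"""

from __future__ import annotations

import warnings
from types import SimpleNamespace

import numpy as np
import pytest

from filmrecon.pipeline import (
    PipelineConfig,
    pose_recovery_errors,
    run_evaluation,
    run_reconstruction,
)
from filmrecon.synth import (
    FilmRenderSpec,
    PhantomSpec,
    make_phantom,
    make_reference,
    render_films,
)

STUDY_SEEDS = (0, 1, 2)


def make_study(seed: int, render_kwargs: dict | None = None):
    """One synthetic study: phantom, films, sidecar, reference, ground truth."""
    vol, brain, skull = make_phantom(PhantomSpec(seed=seed))
    spec = FilmRenderSpec(seed=seed, **(render_kwargs or {}))
    sheets, sidecar, gt = render_films(vol, brain, skull, spec)
    reference = make_reference(vol, brain, skull, atrophy_factor=0.95)
    return SimpleNamespace(
        phantom=vol,
        brain_label=brain,
        skull_label=skull,
        sheets=sheets,
        sidecar=sidecar,
        gt=gt,
        reference=reference,
    )


@pytest.fixture(scope="session")
def phantom_seed1():
    vol, brain, skull = make_phantom(PhantomSpec(seed=1))
    return SimpleNamespace(volume=vol, brain=brain, skull=skull)


@pytest.fixture(scope="session")
def study_runs():
    """Full reconstructions of the three standard synthetic studies."""
    runs = {}
    for seed in STUDY_SEEDS:
        study = make_study(seed)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            result = run_reconstruction(
                study.sheets, study.sidecar, study.reference, PipelineConfig(seed=seed)
            )
            errors = pose_recovery_errors(
                study.gt, result.neighbour_poses, result.final_poses
            )
            evaluation = run_evaluation(
                result.variants, study.gt.sharp_stack, study.gt.brain_mask
            )
        runs[seed] = SimpleNamespace(
            study=study, result=result, errors=errors, evaluation=evaluation
        )
    return runs


@pytest.fixture(scope="session")
def ablation_run():
    """Seed-0 study reconstructed without the inter-slice term (lam_N = 0)."""
    study = make_study(0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        result = run_reconstruction(
            study.sheets, study.sidecar, study.reference, PipelineConfig(seed=0, lam_n=0.0)
        )
        errors = pose_recovery_errors(study.gt, result.neighbour_poses, result.final_poses)
    return SimpleNamespace(study=study, result=result, errors=errors)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
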