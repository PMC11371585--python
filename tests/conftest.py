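"""Shared fixtures: phantoms and acquisitions small enough for fast tests
but large enough that registration and surface sampling are meaningful.
All randomness is seeded; session scope amortizes the heavier builds.
"""
from __future__ import annotations

import numpy as np
import pytest

import aslreg as ar


@pytest.fixture(scope="session")
def fast_spec() -> ar.PhantomSpec:
    """Noise-free phantom at reduced grids for registration tests."""
    return ar.PhantomSpec(
        structural_shape=(48, 48, 40),
        structural_spacing=(2.5, 2.5, 2.5),
        asl_shape=(40, 40, 24),
        asl_spacing=(3.75, 3.75, 3.75),
        mesh_subdivisions=4,
        noise_sd=0.0,
        seed=3,
    )


@pytest.fixture(scope="session")
def tiny_spec() -> ar.PhantomSpec:
    """Smallest usable phantom for structural/plumbing tests."""
    return ar.PhantomSpec(
        structural_shape=(32, 32, 28),
        structural_spacing=(3.5, 3.5, 3.5),
        asl_shape=(24, 24, 16),
        asl_spacing=(5.5, 5.5, 5.5),
        mesh_subdivisions=3,
        noise_sd=0.0,
        seed=4,
    )


@pytest.fixture(scope="session")
def phantom(fast_spec):
    """(structural, tissue_labels, boundary) for the fast spec."""
    return ar.generate_phantom(fast_spec)


@pytest.fixture(scope="session")
def cbf_truth(fast_spec, phantom):
    _, labels, _ = phantom
    return ar.baseline_cbf_map(fast_spec, labels)


@pytest.fixture(scope="session")
def acq_params() -> ar.AcquisitionParams:
    return ar.AcquisitionParams()


@pytest.fixture(scope="session")
def moved_participant(fast_spec, phantom, cbf_truth, acq_params):
    """One noise-free participant acquired under a known rigid transform,
    with the quantified mean-CBF map: the standard registration testbed."""
    _, labels, boundary = phantom
    rng = np.random.default_rng(1)
    true_t = ar.RigidTransform(rng.uniform(-5, 5, 3), rng.uniform(-5, 5, 3))
    acq = ar.generate_asl_series(
        labels, cbf_truth, acq_params, fast_spec, true_transform=true_t, rng=rng
    )
    cbf = ar.quantify_series(acq.series, acq.m0, acq_params)
    return {"true_transform": true_t, "acq": acq, "cbf": cbf, "boundary": boundary}


@pytest.fixture(scope="session")
def small_experiment():
    """A complete small cohort experiment exercising every pipeline stage
    (three groups, injected hypoperfusion, default noise and operator
    error). Shared by the consistency-ordering and pipeline tests."""
    spec = ar.PhantomSpec(
        structural_shape=(48, 48, 40),
        structural_spacing=(2.5, 2.5, 2.5),
        asl_shape=(40, 40, 24),
        asl_spacing=(3.75, 3.75, 3.75),
        mesh_subdivisions=4,
        noise_sd=1.0,
        seed=7,
    )
    effects = [
        ar.GroupEffectSpec(
            group="tau_like", affected_rois=(3, 4, 5),
            cbf_reduction_fraction=0.25, severity_slope=-1.5,
            severity_noise_sd=2.0,
        ),
        ar.GroupEffectSpec(
            group="tdp_like", affected_rois=(10, 11, 12),
            cbf_reduction_fraction=0.25, severity_slope=-1.5,
            severity_noise_sd=2.0,
        ),
    ]
    cfg = ar.ExperimentConfig(
        n_per_group={"control": 5, "tau_like": 4, "tdp_like": 4},
        effects=effects, phantom=spec, seed=11,
    )
    return ar.run_experiment(cfg)
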