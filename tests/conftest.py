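"""Shared fixtures: phantoms are generated programmatically at test time.

The expensive objects (the 20-subject Fabry cohort used by the acceptance
tests, the noiseless mean-anatomy subjects) are session-scoped so each is
built exactly once per run.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pytest

from pntquant.phantom import PhantomSpec, build_phantom, generate_cohort, preset
from pntquant.segmentation import segment_subject
from pntquant.stats import measure_cohort


def make_bare_spec(**overrides) -> PhantomSpec:
    """A small, fast phantom with no papillary muscles or trabeculae."""
    base = dict(
        long_axis_length=80.0,
        cavity_semiaxes_ed=(20.0, 20.0),
        wall_thickness_ed=7.0,
        wall_thickness_es=9.0,
        papillary_count=0,
        papillary_radius=0.0,
        trabecular_amplitude_ed=0.0,
        trabecular_amplitude_es=0.0,
        noise_sd=0.0,
        velocity_noise_sd=0.0,
        n_phases=6,
        supersampling_factor=2,
    )
    base.update(overrides)
    return PhantomSpec(**base)


@pytest.fixture(scope="session")
def bare_subject():
    """Noiseless half-ellipsoid phantom without P&T (analytic limit case)."""
    spec = make_bare_spec()
    cine, velocity, truth = build_phantom(spec, seed=11)
    return spec, cine, velocity, truth


@pytest.fixture(scope="session")
def fabry_noiseless():
    """Noiseless mean-anatomy Fabry subject with its segmentation."""
    spec = dataclasses.replace(preset("fabry").mean_spec, noise_sd=0.0, velocity_noise_sd=0.0)
    cine, velocity, truth = build_phantom(spec, seed=7)
    seg = segment_subject(cine)
    return spec, cine, velocity, truth, seg


@pytest.fixture(scope="session")
def control_noiseless():
    spec = dataclasses.replace(preset("control").mean_spec, noise_sd=0.0, velocity_noise_sd=0.0)
    cine, velocity, truth = build_phantom(spec, seed=7)
    seg = segment_subject(cine)
    return spec, cine, velocity, truth, seg


@pytest.fixture(scope="session")
def fabry_cohort_measured():
    """The full synthetic study cohort: n = 20 Fabry subjects at default
    noise, measured end-to-end (segmentation, quantification, flow)."""
    records = generate_cohort("fabry", 20, 42)
    return measure_cohort(records)


@pytest.fixture(scope="session")
def small_cohort():
    """Four fast Fabry subjects for repeatability/pipeline tests."""
    return generate_cohort(
        "fabry", 4, 3, n_phases=6, supersampling_factor=1, pixel_spacing=2.0
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
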