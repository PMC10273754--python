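"""Shared fixtures: small synthetic cohorts generated at test time."""

from __future__ import annotations

import numpy as np
import pytest

from delaynet.synthetic import (
    design_from_config,
    reduced_design_config,
    simulate_cohort,
    write_cohort,
)


@pytest.fixture(scope="session")
def small_cohort():
    """20 subjects (5 per group), 30 regions, 120 timepoints."""
    cfg = reduced_design_config(n_regions=30, n_per_group=(5, 5, 5, 5), n_timepoints=120)
    design = design_from_config(cfg, seed=11)
    return simulate_cohort(design, 30, 120, seed=11)


@pytest.fixture(scope="session")
def small_cohort_dir(small_cohort, tmp_path_factory):
    directory = tmp_path_factory.mktemp("cohort")
    write_cohort(small_cohort, directory)
    return directory


@pytest.fixture()
def rng():
    return np.random.default_rng(20260921)
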