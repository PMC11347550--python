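"""Shared fixtures: small phantom cohorts generated at test time."""

from __future__ import annotations

import numpy as np
import pytest

from ctprog.phantom import PhantomConfig, generate_cohort
from ctprog.preprocess import assemble_pack


@pytest.fixture(scope="session")
def small_cohort():
    """Eight patients at reduced volume resolution; exercises LOCF and tumors."""
    cfg = PhantomConfig(n_patients=8, volume_shape=(12, 48, 48), seed=42,
                        p_missing_chest_followup=0.3)
    vols, records, lp = generate_cohort(cfg)
    return cfg, vols, records, lp


@pytest.fixture(scope="session")
def small_packs(small_cohort):
    _, vols, _, _ = small_cohort
    return [assemble_pack(v) for v in vols]


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
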