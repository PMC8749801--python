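"""Shared fixtures: the default study phantom and normalized case-1 samplers.

Everything heavy is session-scoped; dose evaluation is analytic and
deterministic, so sharing samplers across tests is safe.
"""

from __future__ import annotations

import numpy as np
import pytest

from pmbat import (
    DoseSampler,
    build_case_plans,
    make_head_phantom,
    make_ptv,
    normalize_to_ptv_mean,
    ptv_sample_points,
)


@pytest.fixture(scope="session")
def phantom():
    return make_head_phantom()


@pytest.fixture(scope="session")
def case1(phantom):
    """Case 1 (13 arrays / 15 deg / 4 mm ctc / 20 mm PTV): spec, PTV, plans."""
    spec, ptv, plans = build_case_plans(1)
    return spec, ptv, plans


@pytest.fixture(scope="session")
def case1_samplers(phantom, case1):
    """pMBAT / pMBRT / PAT samplers normalized to mean PTV dose 1."""
    _, ptv, plans = case1
    pts = ptv_sample_points(ptv)
    return {
        name: normalize_to_ptv_mean(DoseSampler(plan, phantom), pts)
        for name, plan in plans.items()
    }


@pytest.fixture(scope="session")
def ptv20(phantom):
    return make_ptv(phantom, 20.0)
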