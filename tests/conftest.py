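"""Shared fixtures: the expensive converged runs are computed once per
session and reused by the unit, property and acceptance tests."""
import pytest

from dialysim.cases import comparison_case, validation_case, CASE_IDS
from dialysim.driver import run_coupled


@pytest.fixture(scope="session")
def all13():
    """Converged results for the 13 comparison configurations (level-1.0
    meshes, the study resolutions)."""
    return {cid: run_coupled(comparison_case(cid, level=1.0)) for cid in CASE_IDS}


@pytest.fixture(scope="session")
def validation_runs():
    """Converged in-vitro validation runs (saline both sides) at blood
    flows 200 and 300 mL/min."""
    return {qb: run_coupled(validation_case(qb, level=1.0))
            for qb in (200, 300)}


@pytest.fixture(scope="session")
def counterflow_run():
    """Converged uniform-U counter-flow cuboid plus its 1-D oracle."""
    from dialysim.reference import make_fixture
    fx = make_fixture("counterflow_box")
    return fx, run_coupled(fx["case"])
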