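"""Shared fixtures: default cells and noiseless sweep batteries.

Everything is generated at test time by the simulator; session scope keeps
the (cheap but not free) sweep batteries from being re-integrated per test.
"""

from __future__ import annotations

import numpy as np
import pytest

from ionclamp import simulate as sim


@pytest.fixture(scope="session")
def mock_cell() -> sim.SimCellParams:
    return sim.mock_default()


@pytest.fixture(scope="session")
def cln1_cell() -> sim.SimCellParams:
    return sim.cln1_default()


@pytest.fixture(scope="session")
def mock_capacitance_sweep(mock_cell):
    return sim.simulate_sweep(mock_cell, sim.capacitance_protocol())


@pytest.fixture(scope="session")
def tail_batteries(mock_cell, cln1_cell):
    """Noiseless tail batteries for both fixture genotypes."""
    return {
        cell.genotype: {
            v: sim.simulate_sweep(cell, sim.tail_protocol(v)) for v in sim.TAIL_VOLTAGES
        }
        for cell in (mock_cell, cln1_cell)
    }


@pytest.fixture(scope="session")
def pharm_sweeps(mock_cell, cln1_cell):
    """Drug-sequence (+70 mV) sweeps for both fixture genotypes."""
    return {
        cell.genotype: {
            drug: sim.simulate_sweep(cell, sim.tail_protocol(70.0), drug=drug)
            for drug in sim.DRUGS
        }
        for cell in (mock_cell, cln1_cell)
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(20260920)
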