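import numpy as np
import pandas as pd
import pytest

from milletmap.panel_io import GenotypePanel, MarkerDef, PhenotypeTable
from milletmap.synthetic_panel import SimConfig, simulate_panel


def make_panel(calls, line_ids=None, marker_ids=None, **kw):
    """Build a GenotypePanel from a nested list of (a, b) call pairs."""
    calls = np.asarray(calls, dtype=np.int32)
    n, L = calls.shape[:2]
    line_ids = line_ids or [f"L{i + 1}" for i in range(n)]
    markers = [MarkerDef(m) for m in (marker_ids or [f"M{j + 1}" for j in range(L)])]
    return GenotypePanel(line_ids, markers, calls, **kw)


@pytest.fixture
def four_line_panel():
    """Four lines, one biallelic marker splitting them 2 + 2."""
    return make_panel(
        [[(100, 100)], [(100, 100)], [(108, 108)], [(108, 108)]],
        line_ids=["a", "b", "c", "d"],
        marker_ids=["mk"],
    )


@pytest.fixture(scope="session")
def default_sim():
    """One default-condition synthetic study (130 lines × 267 SSRs)."""
    return simulate_panel(SimConfig(seed=20260926 % 1000))


@pytest.fixture(scope="session")
def small_sim():
    """A small structured panel for fast structure/association checks."""
    cfg = SimConfig(n_lines=60, n_markers=60, seed=42, planted_qtls=[])
    return simulate_panel(cfg)


def pheno_from_frame(rows):
    return PhenotypeTable(pd.DataFrame(rows))
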