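import numpy as np
import pytest

from dosepaint.dose_optimization import DoseConstraints
from dosepaint.oxygenation import OxygenLookup, default_lookup
from dosepaint.radiobiology import LQParams, OERParams
from dosepaint.tumor_model import BioParams, TumorGrid


@pytest.fixture(scope="session")
def lq():
    return LQParams()


@pytest.fixture(scope="session")
def oer_params():
    return OERParams()


@pytest.fixture(scope="session")
def bio():
    return BioParams()


@pytest.fixture(scope="session")
def constraints():
    return DoseConstraints()


@pytest.fixture(scope="session")
def lookup() -> OxygenLookup:
    """The packaged oxygen lookup (full TOM build takes minutes; the shipped
    table is the package's own output and is regenerated by the acceptance
    pipeline)."""
    return default_lookup()


@pytest.fixture(scope="session")
def tumor_set(bio, lookup):
    """The four virtual tumors, grown once per session."""
    from dosepaint.virtual_tumors import make_tumor_set

    return make_tumor_set(bio, lookup)


def make_toy_grid(viable_counts, vf=0.06, batch=1, mu=1.0e6, side=1.124,
                  host=True) -> TumorGrid:
    """A small fully-masked test lattice with given viable counts per voxel."""
    counts = np.asarray(viable_counts, dtype=float)
    n = counts.size
    shape = (n, 1, 1)
    grid = TumorGrid(shape, side, mu, batch=batch)
    grid.viable[:] = counts.reshape(1, n, 1, 1)
    grid.capillary[:] = vf / (1 - vf) * grid.viable
    grid.tumor_mask[:] = True
    return grid


@pytest.fixture()
def toy_grid():
    return make_toy_grid([1.0e6, 5.0e5, 2.0e5])
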