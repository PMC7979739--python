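import numpy as np
import pytest

from ferrad.chemistry import (Reaction, ReactionScheme, Species, default_scheme)
from ferrad.microphysics import EnvironmentalState, PropertyModel


@pytest.fixture(scope="session")
def scheme():
    return default_scheme()


@pytest.fixture(scope="session")
def props():
    return PropertyModel()


@pytest.fixture()
def reduced_scheme():
    """Two-state photostationary system: photolysis vs first-order recovery."""
    species = [
        Species("AOX", 100.0, category="iron", n_fe=1),
        Species("ARED", 100.0, category="iron", n_fe=1),
    ]
    reactions = [
        Reaction({"AOX": 1}, {"ARED": 1}, "photolytic", name="photo"),
        Reaction({"ARED": 1}, {"AOX": 1}, "unimolecular", 2.0e-3, name="reox"),
    ]
    return ReactionScheme(species, reactions)


def make_result(conc_history, edges, times=None, geometry="sphere",
                species=None, evaporated=None, volatile=("O2",), area=1.0,
                material=None):
    """Assemble a SimulationResult from raw arrays for observable tests."""
    from ferrad.transport import SimulationResult
    conc = np.asarray(conc_history, float)
    nt = conc.shape[0]
    times = np.arange(nt, dtype=float) if times is None else np.asarray(times, float)
    edges = np.asarray(edges, float)
    if edges.ndim == 1:
        edges = np.repeat(edges[None, :], nt, axis=0)
    if evaporated is None:
        evaporated = np.zeros((nt, len(volatile)))
    return SimulationResult(
        times=times, concentrations=conc, edges=edges,
        evaporated=np.asarray(evaporated, float),
        species=list(species), volatile_species=list(volatile),
        geometry=geometry, area=area, material=material)
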