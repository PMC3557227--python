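import itertools

import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

import footprintdock as fd
from footprintdock.synthetic import SimulationConfig, make_toy_complex

# 30-residue test protein whose six tryptic sites sit on known faces of the
# toy receptor helix: residues 5, 8, 12 face the bound ligand, residues
# 17, 21, 28 face away.  Filler residues are varied so that all 28 partial
# fragments have distinct masses (no ambiguous assignments at 0.2 Da).
K_POSITIONS = (5, 8, 12, 17, 21, 28)
INTERFACE_SITES = frozenset({5, 8, 12})
REMOTE_SITES = frozenset({17, 21, 28})


def _make_fixture_sequence() -> fd.ProteinSequence:
    fill = itertools.cycle("GASTVLINQDEFHW")
    residues = "".join(
        "K" if i + 1 in K_POSITIONS else next(fill) for i in range(30)
    )
    return fd.ProteinSequence("recA", residues)


@pytest.fixture(scope="session")
def fixture_seq() -> fd.ProteinSequence:
    return _make_fixture_sequence()


@pytest.fixture(scope="session")
def demo_seq() -> fd.ProteinSequence:
    return fd.ProteinSequence("demo", "ACKDEFRG")


@pytest.fixture(scope="session")
def toy():
    return make_toy_complex(seed=0)


@pytest.fixture()
def sim_config(fixture_seq):
    def _make(**kw) -> SimulationConfig:
        defaults = dict(
            sequence=fixture_seq,
            protected_sites=INTERFACE_SITES | REMOTE_SITES,
            protection=1.0,
            intensity_cv=0.0,
            seed=0,
        )
        defaults.update(kw)
        return SimulationConfig(**defaults)

    return _make


def propensity_pair(seq, sim, tol=0.2):
    """Free/bound propensity tables from a simulation result."""
    free = fd.compute_propensity(seq, fd.TRYPSIN, sim.peaklists, "free", tol=tol)
    bound = fd.compute_propensity(seq, fd.TRYPSIN, sim.peaklists, "bound", tol=tol)
    return free, bound
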