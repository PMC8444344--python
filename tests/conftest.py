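"""Shared fixtures: small dimer systems built programmatically at test time."""

import numpy as np
import pytest

from saptmc import DimerJob, MonomerWorkspace, Molecule
from saptmc.core.geometry import h2_dimer_tshape


@pytest.fixture(scope="session")
def skewed_h2_dimer():
    """H2...H2 with no point-group symmetry and sizable overlap (6-31G)."""
    mola = Molecule.from_list([("H", 0, 0, 0), ("H", 0.2, 0.3, 1.5)])
    molb = Molecule.from_list([("H", 0.3, 3.0, 0.2), ("H", -0.1, 3.4, 1.7)])
    return mola, molb


@pytest.fixture(scope="session")
def skewed_fci_workspace(skewed_h2_dimer):
    mola, molb = skewed_h2_dimer
    job = DimerJob(mola, molb, "6-31g", "fci", "fci")
    return job, MonomerWorkspace(job)


@pytest.fixture(scope="session")
def tshape_workspace():
    """T-shaped H2...H2 near the equilibrium model geometry (aug-cc-pVDZ)."""
    mola, molb = h2_dimer_tshape(1.44, 1.44, 6.21)
    job = DimerJob(mola, molb, "aug-cc-pvdz", "cas(2,5)", "cas(2,5)")
    return job, MonomerWorkspace(job)


@pytest.fixture(scope="session")
def he_h2_dimer():
    mola = Molecule.from_list([("He", 0, 0, 0)])
    molb = Molecule.from_list([("H", 0, 3.5, -0.7), ("H", 0.2, 3.6, 0.7)])
    return mola, molb
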