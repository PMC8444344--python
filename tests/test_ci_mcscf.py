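"""Configuration-interaction solvers and CASSCF cross-checks."""

import numpy as np
import pytest

from saptmc.core.basis import BasisSet
from saptmc.core.ci import (FCISolver, TwoElectronStates, _sign_excite,
                            strings)
from saptmc.core.ci4 import FCI4, product_guess
from saptmc.core.geometry import Molecule
from saptmc.core.integrals import AOIntegrals
from saptmc.core.mcscf import casscf_general, casscf_two_electron
from saptmc.core.mo import transform_eri, transform_matrix
from saptmc.core.scf import rhf


def _random_hamiltonian(n, seed=0):
    rng = np.random.default_rng(seed)
    g = rng.normal(size=(n, n, n, n))
    g = g + g.transpose(1, 0, 2, 3)
    g = g + g.transpose(0, 1, 3, 2)
    g = g + g.transpose(2, 3, 0, 1)
    h = rng.normal(size=(n, n))
    return h + h.T, g


def _operator_hamiltonian(h, g, nelec):
    """Exact determinant Hamiltonian assembled from excitation operators."""
    n = h.shape[0]
    strs = strings(n, nelec // 2)
    ns = len(strs)
    idx = {int(m): i for i, m in enumerate(strs)}

    def exc(p, q):
        A = np.zeros((ns, ns))
        for I, m in enumerate(strs):
            s, m2 = _sign_excite(int(m), p, q)
            if s:
                A[idx[int(m2)], I] = s
        return A

    eye = np.eye(ns)
    Es = {(p, q): np.kron(exc(p, q), eye) + np.kron(eye, exc(p, q))
          for p in range(n) for q in range(n)}
    H = np.zeros((ns * ns, ns * ns))
    for p in range(n):
        for q in range(n):
            H += h[p, q] * Es[p, q]
            for r in range(n):
                for s in range(n):
                    term = Es[p, q] @ Es[r, s]
                    if q == r:
                        term = term - Es[p, s]
                    H += 0.5 * g[p, q, r, s] * term
    return H


@pytest.mark.parametrize("n,nelec", [(4, 2), (4, 4), (5, 4)])
def test_determinant_hamiltonian_vs_operator_algebra(n, nelec):
    h, g = _random_hamiltonian(n)
    sol = FCISolver(h, g, nelec)
    H = _operator_hamiltonian(h, g, nelec)
    assert np.abs(H - sol.H).max() < 1e-10


def test_pair_solver_matches_determinant_singlets():
    h, g = _random_hamiltonian(5, seed=3)
    tes = TwoElectronStates(h, g)
    det = FCISolver(h, g, 2)
    w, V = det.solve_singlets(6)
    assert np.allclose(tes.energies[:6], w[:6], atol=1e-9)


def test_trdm2_partial_trace():
    h, g = _random_hamiltonian(4, seed=5)
    sol = FCISolver(h, g, 4)
    w, V = sol.solve_singlets(1)
    v = V[:, 0]
    d1 = sol.trdm1(v, v)
    d2 = sol.trdm2(v, v)
    n = 4
    # sum_r D[p,q,r,r] = (N-1) gamma_pq
    assert np.allclose(np.einsum("pqrr->pq", d2), 3.0 * d1, atol=1e-10)


def test_fci4_matches_determinant_solver():
    h, g = _random_hamiltonian(5, seed=1)
    ref = FCISolver(h, g, 4)
    f4 = FCI4(h, g)
    C = np.random.default_rng(2).normal(size=(f4.nstr, f4.nstr))
    C = C + C.T
    sig = f4.sigma(C)
    sig_ref = (ref.H @ C.ravel()).reshape(f4.nstr, f4.nstr)
    assert np.abs(sig - sig_ref).max() < 1e-10
    w, V = ref.solve()
    E, Cv = f4.solve(tol=1e-10)
    # lowest singlet of the determinant space
    sing = ref.singlet_indices()
    assert abs(E - w[sing[0]]) < 1e-8


def test_fci4_size_consistency_he2():
    """He2 at 5.6 bohr: the dimer FCI energy is two isolated He atoms."""
    mol = Molecule.from_list([("He", 0, 0, 0), ("He", 0, 0, 5.6)])
    b = BasisSet(mol, "cc-pvdz")
    ints = AOIntegrals(b)
    e, C, weps, dm = rhf(ints.hcore, ints.eri, ints.S, 4,
                         ints.nuclear_repulsion)
    h = transform_matrix(ints.hcore, C)
    g = transform_eri(ints.eri, C)
    f4 = FCI4(h, g, enuc=ints.nuclear_repulsion)
    E, _ = f4.solve(tol=1e-9)
    assert abs(E - (-5.775194486)) < 5e-7   # 2 x He FCI/cc-pVDZ (ghost-free)


def test_casscf_two_electron_variational_ordering():
    mol = Molecule.from_list([("H", 0, 0, 0), ("H", 0, 0, 1.4)])
    b = BasisSet(mol, "cc-pvdz")
    ints = AOIntegrals(b)
    e, C, weps, dm = rhf(ints.hcore, ints.eri, ints.S, 2,
                         ints.nuclear_repulsion)
    h = transform_matrix(ints.hcore, C)
    g = transform_eri(ints.eri, C)
    tes = TwoElectronStates(h, g, enuc=ints.nuclear_repulsion)
    r2 = casscf_two_electron(h, g, 2, enuc=ints.nuclear_repulsion)
    r5 = casscf_two_electron(h, g, 5, enuc=ints.nuclear_repulsion)
    assert r2.converged and r5.converged
    assert e > r2.energy > r5.energy > tes.energies[0]
    # general optimizer agrees with the two-electron fast path
    rg = casscf_general(h, g, 0, 2, 2, enuc=ints.nuclear_repulsion)
    assert abs(rg.energy - r2.energy) < 1e-8


def test_state_averaged_casscf_paths_agree():
    mol = Molecule.from_list([("H", 0, 0, 0), ("H", 0, 0, 1.4)])
    b = BasisSet(mol, "cc-pvdz")
    ints = AOIntegrals(b)
    e, C, weps, dm = rhf(ints.hcore, ints.eri, ints.S, 2,
                         ints.nuclear_repulsion)
    h = transform_matrix(ints.hcore, C)
    g = transform_eri(ints.eri, C)
    rs1 = casscf_two_electron(h, g, 3, n_avg=3, enuc=ints.nuclear_repulsion)
    rs2 = casscf_general(h, g, 0, 3, 2, n_avg=3, enuc=ints.nuclear_repulsion)
    assert abs(rs1.energy - rs2.energy) < 1e-7
    assert np.allclose(rs1.state_energies[:3], rs2.state_energies[:3],
                       atol=1e-6)
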