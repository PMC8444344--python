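"""ERPA construction and solution checks."""

import numpy as np
import pytest

from saptmc import (DimerJob, Molecule, MonomerWorkspace, build_integrals,
                    build_pair_index, compute_monomer_ensemble,
                    erpa_ab_matrices, no_basis_blocks, solve_erpa)
from saptmc.core.ci import FCISolver, TwoElectronStates
from saptmc.core.mo import transform_eri
from saptmc.erpa import solve_erpa_dense, transition_1rdms
from saptmc.monomer import ThresholdSet


@pytest.fixture(scope="module")
def h2_monomer_erpa():
    mola = Molecule.from_list([("H", 0, 0, 0), ("H", 0, 0, 1.4)])
    molb = Molecule.from_list([("H", 0, 4.5, 0), ("H", 0, 4.5, 1.4)])

    def make(method):
        job = DimerJob(mola, molb, "6-31g", method, method)
        ws = MonomerWorkspace(job)
        st = compute_monomer_ensemble(job, "A", ws)[0]
        sb = compute_monomer_ensemble(job, "B", ws)[0]
        ints = build_integrals(st, sb, ws)
        U = ints.U_a
        st.h_no = U.T @ ws.h_X("A") @ U
        g_no = transform_eri(ws.g_X, U)
        pairs = build_pair_index(st, job.thresholds)
        A, B, m = erpa_ab_matrices(st, no_basis_blocks(g_no, st.n_occupied),
                                   pairs)
        return job, ws, st, g_no, pairs, A, B, m
    return make


def test_hf_reference_reduces_to_rpa(h2_monomer_erpa):
    """With a determinant reference the ERPA equations are singlet TDHF;
    excitation energies must match an independently built RPA."""
    job, ws, st, g_no, pairs, A, B, m = h2_monomer_erpa("hf")
    sol = solve_erpa(A, B, m, pairs)
    n = g_no.shape[0]
    # independent TDHF over canonical monomer orbitals
    F = st.h_no + 2 * np.einsum("pqii->pq", g_no[:, :, :1, :1]) \
        - np.einsum("piiq->pq", g_no[:, :1, :1, :])
    eps, C = np.linalg.eigh(F)
    g_c = transform_eri(g_no, C)
    occ = 0
    nv = n - 1
    Ar = np.zeros((nv, nv))
    Br = np.zeros((nv, nv))
    for ia in range(nv):
        a = ia + 1
        for jb in range(nv):
            b = jb + 1
            Ar[ia, jb] = (eps[a] - eps[occ]) * (a == b) \
                + 2 * g_c[occ, a, occ, b] - g_c[occ, occ, a, b]
            Br[ia, jb] = 2 * g_c[occ, a, occ, b] - g_c[occ, b, occ, a]
    w2 = np.linalg.eigvals((Ar - Br) @ (Ar + Br))
    w_ref = np.sort(np.sqrt(np.abs(w2)))
    assert np.allclose(np.sort(sol.omega), w_ref, atol=1e-9)


def test_matrices_symmetric(h2_monomer_erpa):
    job, ws, st, g_no, pairs, A, B, m = h2_monomer_erpa("cas(2,3)")
    # symmetry holds to the accuracy of the orbital optimization
    assert np.abs(A - A.T).max() < 1e-7
    assert np.abs(B - B.T).max() < 1e-7


def test_erpa_matrices_vs_exact_double_commutators(h2_monomer_erpa):
    """<[E_ab,[H,E_rs]]> from the RDM contraction formulas against literal
    operator algebra on the embedded CI vector."""
    job, ws, st, g_no, pairs, A, B, m = h2_monomer_erpa("cas(2,3)")
    n = g_no.shape[0]
    # embed the CAS(2,3) state in the full two-electron determinant space
    sol = FCISolver(st.h_no, g_no, 2)
    ns = len(sol.stra)
    civec = np.zeros(ns * ns)
    G = st.geminal
    for i in range(n):
        for j in range(n):
            civec[i * ns + j] = G[i, j]
    Hfull = sol.H

    def dc(a, b, r, s):
        t_rs = sol.apply_epq(civec, r, s)
        t_ba = sol.apply_epq(civec, b, a)      # E_ab^dagger |psi>
        term1 = t_ba @ (Hfull @ t_rs)
        term2 = t_ba @ sol.apply_epq(Hfull @ civec, r, s)
        term3 = (Hfull @ civec) @ sol.apply_epq(sol.apply_epq(civec, a, b),
                                                r, s)
        term4 = sol.apply_epq(civec, s, r) @ (Hfull @ sol.apply_epq(civec,
                                                                    a, b))
        return term1 - term2 - term3 + term4

    rng = np.random.default_rng(1)
    for _ in range(6):
        i = int(rng.integers(len(pairs)))
        j = int(rng.integers(len(pairs)))
        p, q = pairs.pairs[i]
        r, s = pairs.pairs[j]
        assert abs(A[i, j] - dc(q, p, r, s)) < 1e-9
        assert abs(B[i, j] - dc(q, p, s, r)) < 1e-9


def test_ground_state_roots_positive_and_normalized(h2_monomer_erpa):
    job, ws, st, g_no, pairs, A, B, m = h2_monomer_erpa("cas(2,3)")
    sol = solve_erpa(A, B, m, pairs)
    assert (sol.omega > 0).all()
    nrm = np.einsum("p,pk,pk->k", sol.metric, sol.X, sol.X) \
        - np.einsum("p,pk,pk->k", sol.metric, sol.Y, sol.Y)
    assert np.abs(nrm - 1.0).max() < 1e-8


def test_dense_and_reduced_solvers_agree(h2_monomer_erpa):
    job, ws, st, g_no, pairs, A, B, m = h2_monomer_erpa("fci")
    sol = solve_erpa(A, B, m, pairs)
    sold = solve_erpa_dense(0.5 * (A + A.T), 0.5 * (B + B.T), m, pairs)
    dw = np.abs(np.sort(sol.omega) - np.sort(sold.omega))
    assert (dw / np.maximum(1.0, np.sort(sol.omega))).max() < 1e-9


def test_exact_reference_recovers_exact_gaps(h2_monomer_erpa):
    """ERPA on the exact two-electron ground state reproduces the dominant
    singly-excited singlet gaps of the exact spectrum."""
    job, ws, st, g_no, pairs, A, B, m = h2_monomer_erpa("fci")
    sol = solve_erpa(A, B, m, pairs)
    tes = TwoElectronStates(ws.h_X("A"), ws.g_X, enuc=ws.enuc("A"))
    gaps = tes.energies[1:] - tes.energies[0]
    # the lowest ERPA root matches the lowest exact gap tightly
    assert abs(np.sort(sol.omega)[0] - gaps[0]) < 1e-6


def test_degenerate_pair_filter():
    """Exactly degenerate active occupations are discarded (they would make
    the ERPA metric singular); the discard list reports them."""
    from saptmc.monomer import MonomerState
    occ = np.array([0.5, 0.5, 0.0, 0.0])
    st = MonomerState(no_coeffs=np.eye(4), occ=occ, rdm2=None,
                      n_electrons=2, state_index=0, energy=0.0,
                      s1=np.arange(0), s2=np.arange(2), s3=np.arange(2, 4),
                      method="cas(2,2)", geminal=np.diag([2**-.5, -2**-.5]),
                      n_occupied=2)
    pi = build_pair_index(st, ThresholdSet())
    assert (1, 0) in [tuple(p) for p in pi.discarded]
    assert (1, 0) not in [tuple(p) for p in pi.pairs]
    # every retained pair carries a safely nonsingular metric
    assert np.abs(pi.metric).min() > 1e-10


def test_phase_flip_leaves_transition_densities_quadratic(h2_monomer_erpa):
    """Flipping an eigenvector's sign flips the 1-TRDM sign; any energy
    (quadratic in the TRDM) is unchanged."""
    job, ws, st, g_no, pairs, A, B, m = h2_monomer_erpa("cas(2,3)")
    sol = solve_erpa(A, B, m, pairs)
    g1 = transition_1rdms(sol)
    sol.X[:, 0] *= -1
    sol.Y[:, 0] *= -1
    g2 = transition_1rdms(sol)
    assert np.abs(g1[0] + g2[0]).max() < 1e-12
    assert np.abs(g1[1:] - g2[1:]).max() < 1e-12


def test_erpa_solution_roundtrip(tmp_path, h2_monomer_erpa):
    from saptmc.erpa import ERPASolution
    job, ws, st, g_no, pairs, A, B, m = h2_monomer_erpa("cas(2,3)")
    sol = solve_erpa(A, B, m, pairs)
    p = tmp_path / "erpa_a.h5"
    sol.save(p)
    sol2 = ERPASolution.load(p)
    assert np.array_equal(sol.omega, sol2.omega)
    assert np.array_equal(sol.X, sol2.X)
    assert np.array_equal(sol.pairs.pairs, sol2.pairs.pairs)
    assert sol2.reference_state_index == 0
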