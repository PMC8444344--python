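"""Single-exchange (S^2) matrix elements against explicit tensor algebra.

The reference applies the transposition sum P1 and the intermolecular
operator V literally to explicit few-electron wave-function tensors; the
package's geminal and density-matrix contraction formulas must agree to
machine precision.
"""

import numpy as np
import pytest

from saptmc import (DimerJob, Molecule, MonomerWorkspace, build_integrals,
                    compute_monomer_ensemble, electrostatic_energy,
                    exchange_s2_energy)
from saptmc.contractions import GeminalPairContractions
from saptmc.core.ci import FCISolver, TwoElectronStates
from saptmc.core.geometry import interaction_nuclear_repulsion
from saptmc.first_order import _general_p1_vp1, general_p1_vp1_kernels
from saptmc.oracles import (ProductOracle, ci_tensor, geminal_tensor,
                            spin_orbital_one_body, spin_orbital_two_body)


@pytest.fixture(scope="module")
def close_dimer():
    """Skewed H2...H2 at short range: large overlaps, no symmetry."""
    mola = Molecule.from_list([("H", 0, 0, 0), ("H", 0.3, 0.2, 1.6)])
    molb = Molecule.from_list([("H", 0.5, 3.1, 0.4), ("H", -0.2, 3.6, 1.9)])
    job = DimerJob(mola, molb, "6-31g", "fci", "fci")
    ws = MonomerWorkspace(job)
    tA = TwoElectronStates(ws.h_X("A"), ws.g_X, enuc=ws.enuc("A"))
    tB = TwoElectronStates(ws.h_X("B"), ws.g_X, enuc=ws.enuc("B"))
    orc = ProductOracle(2, 2)
    vnn = interaction_nuclear_repulsion(mola, molb)
    ops = orc.interaction_tensors(
        spin_orbital_one_body(ws._v["A"]), spin_orbital_one_body(ws._v["B"]),
        spin_orbital_two_body(ws.g_X), vnn)
    return job, ws, tA, tB, orc, ops, vnn


@pytest.mark.parametrize("ket_a,ket_b", [(0, 0), (2, 0), (1, 3)])
def test_geminal_master_formulas_vs_tensor_oracle(close_dimer, ket_a, ket_b):
    job, ws, tA, tB, orc, ops, vnn = close_dimer
    gc = GeminalPairContractions(ws.g_X, ws._v["A"], ws._v["B"], vnn)
    GA0, GB0 = tA.geminals[0], tB.geminals[0]
    GAk, GBk = tA.geminals[ket_a], tB.geminals[ket_b]
    bra = orc.product(geminal_tensor(GA0), geminal_tensor(GB0))
    ket = orc.product(geminal_tensor(GAk), geminal_tensor(GBk))
    p1_ref = orc.overlap(bra, orc.apply_p1(ket))
    vp1_ref = orc.overlap(bra, orc.apply_V(orc.apply_p1(ket), ops))
    v_ref = orc.overlap(bra, orc.apply_V(ket, ops))
    assert abs(gc.p1(GA0, GAk, GB0, GBk) - p1_ref) < 1e-12
    assert abs(gc.v_p1(GA0, GAk, GB0, GBk) - vp1_ref) < 1e-12
    assert abs(gc.v_pol(GA0, GAk, GB0, GBk) - v_ref) < 1e-12


def test_first_order_exchange_vs_truncated_antisymmetrizer(close_dimer):
    """E_exch^(1)(S^2) equals the explicit (V - E_elst)(-P1) expectation."""
    job, ws, tA, tB, orc, ops, vnn = close_dimer
    sa = compute_monomer_ensemble(job, "A", ws)[0]
    sb = compute_monomer_ensemble(job, "B", ws)[0]
    ints = build_integrals(sa, sb, ws)
    e_exch = exchange_s2_energy(sa, sb, ints)
    e_elst = electrostatic_energy(sa, sb, ints)
    T0 = orc.product(geminal_tensor(tA.geminals[0]),
                     geminal_tensor(tB.geminals[0]))
    P1T0 = orc.apply_p1(T0)
    ref = -(orc.overlap(T0, orc.apply_V(P1T0, ops))
            - e_elst * orc.overlap(T0, P1T0))
    assert abs(e_exch - ref) < 1e-12


def test_general_kernels_match_geminal_path(close_dimer):
    job, ws, tA, tB, orc, ops, vnn = close_dimer
    sa = compute_monomer_ensemble(job, "A", ws)[0]
    sb = compute_monomer_ensemble(job, "B", ws)[0]
    ints = build_integrals(sa, sb, ws)
    _, inter = exchange_s2_energy(sa, sb, ints, return_intermediates=True)
    p1g, vp1g = _general_p1_vp1(sa, sb, ints)
    assert abs(inter.p1 - p1g) < 1e-12
    assert abs(inter.v_p1 - vp1g) < 1e-12


def test_general_kernels_four_electron_monomer():
    """Density-matrix S^2 formulas for a 4-electron monomer vs 6-electron
    explicit tensor algebra (He2...He, minimal basis)."""
    mola = Molecule.from_list([("He", 0, 0, 0), ("He", 0, 0.3, 1.6)])
    molb = Molecule.from_list([("He", 0.4, 2.6, 0.8)])
    job = DimerJob(mola, molb, "sto-3g", "fci", "hf")
    ws = MonomerWorkspace(job)
    g = ws.g_X
    fa = FCISolver(ws.h_X("A"), g, 4)
    wv, Vv = fa.solve_singlets(1)
    v0 = Vv[:, 0]
    d1 = fa.trdm1(v0, v0)
    d2 = fa.trdm2(v0, v0)
    sb = compute_monomer_ensemble(job, "B", ws)[0]
    sa_dummy = compute_monomer_ensemble(job, "B", ws)[0]
    from saptmc.nointegrals import NOIntegrals
    ints = build_integrals(sa_dummy, sb, ws)   # only for gamma_b machinery
    gB = ints.gamma_b_X
    DB = np.einsum("pq,rs->pqrs", gB, gB) \
        - 0.5 * np.einsum("ps,rq->pqrs", gB, gB)
    vnn = interaction_nuclear_repulsion(mola, molb)
    p1, vp1 = general_p1_vp1_kernels(d1.T, d2, gB, DB, ws._v["A"],
                                     ws._v["B"], g, vnn)
    orc = ProductOracle(4, 2)
    TA = ci_tensor(v0, fa.stra, fa.strb, fa.norb, np.eye(g.shape[0]))
    GB = ints.U_b @ sb.geminal @ ints.U_b.T
    T0 = orc.product(TA, geminal_tensor(GB))
    ops = orc.interaction_tensors(
        spin_orbital_one_body(ws._v["A"]), spin_orbital_one_body(ws._v["B"]),
        spin_orbital_two_body(g), vnn)
    assert abs(p1 - orc.overlap(T0, orc.apply_p1(T0))) < 1e-12
    assert abs(vp1 - orc.overlap(T0, orc.apply_V(orc.apply_p1(T0), ops))) < 1e-12


def test_exchange_vanishes_at_long_range():
    """E_exch^(1)(S^2) decays with the intermonomer overlap and is below
    1e-12 hartree at 50 A separation."""
    from saptmc.core.geometry import h2_dimer_tshape
    vals = []
    for sep_ang in (8.0, 50.0):
        mola, molb = h2_dimer_tshape(1.44, 1.44, sep_ang / 0.529177210903)
        j = DimerJob(mola, molb, "cc-pvdz", "cas(2,2)", "cas(2,2)")
        w2 = MonomerWorkspace(j)
        sa = compute_monomer_ensemble(j, "A", w2)[0]
        sb = compute_monomer_ensemble(j, "B", w2)[0]
        ints = build_integrals(sa, sb, w2)
        vals.append(abs(exchange_s2_energy(sa, sb, ints)))
    assert vals[0] > vals[1]
    assert vals[1] < 1e-12


def test_ab_relabeling_invariance(close_dimer):
    job, ws, tA, tB, orc, ops, vnn = close_dimer
    mola, molb = job.geometry_a, job.geometry_b
    j1 = DimerJob(mola, molb, "6-31g", "fci", "fci")
    j2 = DimerJob(molb, mola, "6-31g", "fci", "fci")
    out = []
    for j in (j1, j2):
        w = MonomerWorkspace(j)
        sa = compute_monomer_ensemble(j, "A", w)[0]
        sb = compute_monomer_ensemble(j, "B", w)[0]
        ints = build_integrals(sa, sb, w)
        out.append((electrostatic_energy(sa, sb, ints),
                    exchange_s2_energy(sa, sb, ints)))
    assert abs(out[0][0] - out[1][0]) < 1e-10
    assert abs(out[0][1] - out[1][1]) < 1e-10
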