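"""Second-order energies against explicit Rayleigh-Schrodinger sums.

The reference builds the first-order induction and dispersion wave
functions as explicit tensors over products of exact two-electron monomer
states, then evaluates the S^2 exchange combination with literal operator
algebra.  The package formulas must agree to machine precision when fed
the same exact transition quantities.
"""

import numpy as np
import pytest

from saptmc import (DimerJob, Molecule, MonomerWorkspace, build_integrals,
                    compute_monomer_ensemble, dispersion_energy,
                    electrostatic_energy, exchange_dispersion_energy,
                    exchange_induction_energy, exchange_s2_energy,
                    induction_energy, transitions_from_states)
from saptmc.core.ci import TwoElectronStates
from saptmc.core.geometry import interaction_nuclear_repulsion
from saptmc.oracles import (ProductOracle, geminal_tensor,
                            spin_orbital_one_body, spin_orbital_two_body)
from saptmc.second_pol import dispersion_couplings, induction_couplings


@pytest.fixture(scope="module")
def system():
    mola = Molecule.from_list([("H", 0, 0, 0), ("H", 0.2, 0.3, 1.5)])
    molb = Molecule.from_list([("H", 0.3, 3.0, 0.2), ("H", -0.1, 3.4, 1.7)])
    job = DimerJob(mola, molb, "6-31g", "fci", "fci")
    ws = MonomerWorkspace(job)
    tA = TwoElectronStates(ws.h_X("A"), ws.g_X, enuc=ws.enuc("A"))
    tB = TwoElectronStates(ws.h_X("B"), ws.g_X, enuc=ws.enuc("B"))
    sa = compute_monomer_ensemble(job, "A", ws)[0]
    sb = compute_monomer_ensemble(job, "B", ws)[0]
    ints = build_integrals(sa, sb, ws)
    tsA = transitions_from_states(tA.energies, np.stack(tA.geminals), 0)
    tsB = transitions_from_states(tB.energies, np.stack(tB.geminals), 0)
    orc = ProductOracle(2, 2)
    vnn = interaction_nuclear_repulsion(mola, molb)
    ops = orc.interaction_tensors(
        spin_orbital_one_body(ws._v["A"]), spin_orbital_one_body(ws._v["B"]),
        spin_orbital_two_body(ws.g_X), vnn)
    TAs = [geminal_tensor(G) for G in tA.geminals]
    TBs = [geminal_tensor(G) for G in tB.geminals]
    return job, ws, sa, sb, ints, tsA, tsB, tA, tB, orc, ops, TAs, TBs


@pytest.fixture(scope="module")
def reference(system):
    """Explicit sum-over-states perturbation theory + first-order tensors."""
    job, ws, sa, sb, ints, tsA, tsB, tA, tB, orc, ops, TAs, TBs = system
    T00 = orc.product(TAs[0], TBs[0])
    VT00 = orc.apply_V(T00, ops)
    out = {"T00": T00, "e_elst": orc.overlap(T00, VT00)}
    e_ind_ab = e_ind_ba = e_disp = 0.0
    T_ind_A = np.zeros_like(T00)
    T_ind_B = np.zeros_like(T00)
    T_disp = np.zeros_like(T00)
    for mu in range(1, tA.n_states):
        v = orc.overlap(orc.product(TAs[mu], TBs[0]), VT00)
        w = tA.energies[mu] - tA.energies[0]
        e_ind_ab -= v * v / w
        T_ind_A += (-v / w) * orc.product(TAs[mu], TBs[0])
    for nu in range(1, tB.n_states):
        v = orc.overlap(orc.product(TAs[0], TBs[nu]), VT00)
        w = tB.energies[nu] - tB.energies[0]
        e_ind_ba -= v * v / w
        T_ind_B += (-v / w) * orc.product(TAs[0], TBs[nu])
    for mu in range(1, tA.n_states):
        TmuB = [orc.product(TAs[mu], TBs[nu]) for nu in range(tB.n_states)]
        for nu in range(1, tB.n_states):
            v = orc.overlap(TmuB[nu], VT00)
            w = (tA.energies[mu] - tA.energies[0]
                 + tB.energies[nu] - tB.energies[0])
            e_disp -= v * v / w
            T_disp += (-v / w) * TmuB[nu]
    out.update(e_ind_ab=e_ind_ab, e_ind_ba=e_ind_ba, e_disp=e_disp,
               T_ind_A=T_ind_A, T_ind_B=T_ind_B, T_disp=T_disp)

    def exch2(T1, e_pol):
        P1T1 = orc.apply_p1(T1)
        t = orc.overlap(T00, orc.apply_V(P1T1, ops))
        t -= out["e_elst"] * orc.overlap(T00, P1T1)
        t -= orc.overlap(T00, orc.apply_p1(T00)) * e_pol
        return -t   # fermionic sign of single transpositions

    out["exch_ind_ab"] = exch2(T_ind_A, e_ind_ab)
    out["exch_ind_ba"] = exch2(T_ind_B, e_ind_ba)
    out["exch_disp"] = exch2(T_disp, e_disp)
    return out


def test_polarization_energies_vs_sum_over_states(system, reference):
    job, ws, sa, sb, ints, tsA, tsB, *_ = system
    e_ind, e_ab, e_ba = induction_energy(tsA, tsB, ints)
    e_disp = dispersion_energy(tsA, tsB, ints)
    assert abs(e_ab - reference["e_ind_ab"]) < 1e-12
    assert abs(e_ba - reference["e_ind_ba"]) < 1e-12
    assert abs(e_disp - reference["e_disp"]) < 1e-12


def test_exchange_induction_and_dispersion_vs_oracle(system, reference):
    job, ws, sa, sb, ints, tsA, tsB, *_ = system
    _, inter = exchange_s2_energy(sa, sb, ints, return_intermediates=True)
    tot, x_ab, x_ba = exchange_induction_energy(tsA, tsB, sa, sb, ints, inter)
    e_disp = dispersion_energy(tsA, tsB, ints)
    xd = exchange_dispersion_energy(tsA, tsB, sa, sb, ints, inter, e_disp)
    assert abs(x_ab - reference["exch_ind_ab"]) < 1e-12
    assert abs(x_ba - reference["exch_ind_ba"]) < 1e-12
    assert abs(xd - reference["exch_disp"]) < 1e-12


def test_omega_contracted_equals_sum_over_states_coupling(system):
    """The embedding-potential contraction reproduces the explicit
    <00|V|mu 0> matrix element for every transition (the two equivalent
    induction formulations agree to 1e-10)."""
    job, ws, sa, sb, ints, tsA, tsB, tA, tB, orc, ops, TAs, TBs = system
    om_B = ints.embedding_potential_X("B")
    c = induction_couplings(tsA, om_B)
    T00 = orc.product(TAs[0], TBs[0])
    VT00 = orc.apply_V(T00, ops)
    for k, mu in enumerate(range(1, tA.n_states)):
        ref = orc.overlap(orc.product(TAs[mu], TBs[0]), VT00)
        assert abs(c[k] - ref) < 1e-10


def test_dispersion_couplings_match_polarization_elements(system):
    job, ws, sa, sb, ints, tsA, tsB, tA, tB, orc, ops, TAs, TBs = system
    W = dispersion_couplings(tsA, tsB, ints)
    T00 = orc.product(TAs[0], TBs[0])
    VT00 = orc.apply_V(T00, ops)
    rng = np.random.default_rng(0)
    for _ in range(8):
        mu = int(rng.integers(1, tA.n_states))
        nu = int(rng.integers(1, tB.n_states))
        ref = orc.overlap(orc.product(TAs[mu], TBs[nu]), VT00)
        assert abs(W[mu - 1, nu - 1] - ref) < 1e-10


def test_general_exchange_induction_matches_geminal_path_for_hf(he_h2_dimer):
    """Factorized transition 2-RDMs are exact for single-determinant
    monomers: both exchange-induction paths must agree."""
    mola, molb = he_h2_dimer
    job = DimerJob(mola, molb, "cc-pvdz", "hf", "hf")
    ws = MonomerWorkspace(job)
    sa = compute_monomer_ensemble(job, "A", ws)[0]
    sb = compute_monomer_ensemble(job, "B", ws)[0]
    ints = build_integrals(sa, sb, ws)
    from saptmc.workflow import _erpa_transition_set
    tsA = _erpa_transition_set(sa, job, ints, ws, "A")
    tsB = _erpa_transition_set(sb, job, ints, ws, "B")
    # use the literal <0|E|mu> densities of the transition geminals in both
    # paths, so only the 2-RDM factorization itself is under test
    for ts in (tsA, tsB):
        ts.gamma = 2.0 * np.einsum("pq,kqr->kpr", ts.geminal0, ts.geminals)
    _, inter = exchange_s2_energy(sa, sb, ints, return_intermediates=True)
    tot_gem, a_gem, b_gem = exchange_induction_energy(tsA, tsB, sa, sb,
                                                      ints, inter)
    # force the general (density-matrix) path by hiding the geminals
    tsA2 = type(tsA)(tsA.omega, tsA.gamma, 0, None, None)
    tsB2 = type(tsB)(tsB.omega, tsB.gamma, 0, None, None)
    tot_gen, a_gen, b_gen = exchange_induction_energy(tsA2, tsB2, sa, sb,
                                                      ints, inter)
    assert abs(a_gem - a_gen) < 1e-10
    assert abs(b_gem - b_gen) < 1e-10
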