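"""Excited-monomer dispersion/induction: de-excitation corrections."""

import numpy as np
import pytest

from saptmc import (DimerJob, Molecule, MonomerWorkspace, build_integrals,
                    compute_monomer_ensemble, run_sapt,
                    transitions_from_states)
from saptmc.core.ci import TwoElectronStates
from saptmc.core.geometry import h2_dimer_tshape
from saptmc.second_pol import (dispersion_couplings, induction_couplings,
                               split_positive_negative)


@pytest.fixture(scope="module")
def excited_fci():
    """H2 (first excited singlet) ... H2 (ground), exact two-electron states."""
    mola, molb = h2_dimer_tshape(1.44, 1.44, 5.0)
    job = DimerJob(mola, molb, "6-31g**", "fci", "fci", state_a=1)
    ws = MonomerWorkspace(job)
    comps = run_sapt(job, ws)
    tA = TwoElectronStates(ws.h_X("A"), ws.g_X, irreps=ws.labels,
                           enuc=ws.enuc("A"))
    tB = TwoElectronStates(ws.h_X("B"), ws.g_X, irreps=ws.labels,
                           enuc=ws.enuc("B"))
    sa = compute_monomer_ensemble(job, "A", ws)[1]
    sb = compute_monomer_ensemble(job, "B", ws)[0]
    ints = build_integrals(sa, sb, ws)
    tsA = transitions_from_states(tA.energies, np.stack(tA.geminals), 1)
    tsB = transitions_from_states(tB.energies, np.stack(tB.geminals), 0)
    return job, ws, comps, tsA, tsB, ints


def test_signed_full_sum_equals_positive_plus_epsilon(excited_fci):
    """With exact response properties, summing dispersion over the full
    signed spectrum equals the positive-transition part plus the
    de-excitation corrections computed from the lower-state response."""
    job, ws, comps, tsA, tsB, ints = excited_fci
    W = dispersion_couplings(tsA, tsB, ints)
    full = 0.0
    for mu in range(len(tsA.omega)):
        for nu in tsB.positive():
            full -= W[mu, nu] ** 2 / (tsA.omega[mu] + tsB.omega[nu])
    assert abs(full - (comps.e_disp_plus + comps.eps_disp_sum)) < 1e-8


def test_signed_induction_equals_positive_plus_epsilon(excited_fci):
    job, ws, comps, tsA, tsB, ints = excited_fci
    om_B = ints.embedding_potential_X("B")
    c = induction_couplings(tsA, om_B)
    full = -float(np.sum(c ** 2 / tsA.omega))
    routed = comps.e_ind_parts[0] + sum(comps.epsilons["ind"].values())
    assert abs(full - routed) < 1e-10


def test_epsilon_induction_nonnegative(excited_fci):
    job, ws, comps, tsA, tsB, ints = excited_fci
    for v in comps.epsilons["ind"].values():
        assert v >= -1e-14


def test_ground_state_has_no_epsilons():
    mola, molb = h2_dimer_tshape(1.44, 1.44, 5.0)
    job = DimerJob(mola, molb, "6-31g", "fci", "fci")
    comps = run_sapt(job)
    assert comps.eps_ind_sum == 0.0 and comps.eps_disp_sum == 0.0
    assert comps.e_int == comps.e_int_star


def test_negative_transitions_off_switch():
    mola, molb = h2_dimer_tshape(1.44, 1.44, 5.0)
    job = DimerJob(mola, molb, "6-31g**", "fci", "fci", state_a=1,
                   negative_transitions=False)
    comps = run_sapt(job)
    assert comps.eps_disp_sum == 0.0
    assert comps.e_int == comps.e_int_star


def test_deexcitation_in_doubly_excited_reference():
    """The second excited two-electron singlet is closed-shell-like, so its
    ERPA spectrum is well defined and contains the de-excitation to the
    open-shell singlet below it with the exact (negative) gap."""
    from saptmc.erpa import (build_pair_index, erpa_ab_matrices,
                             no_basis_blocks, solve_erpa)
    from saptmc.core.mo import transform_eri
    mola, molb = h2_dimer_tshape(1.44, 1.44, 30.0)
    job = DimerJob(mola, molb, "sto-3g", "fci", "fci", state_a=2)
    ws = MonomerWorkspace(job)
    sa = compute_monomer_ensemble(job, "A", ws, n_states=3)[2]
    sb = compute_monomer_ensemble(job, "B", ws)[0]
    ints = build_integrals(sa, sb, ws)
    U = ints.U_a
    sa.h_no = U.T @ ws.h_X("A") @ U
    g_no = transform_eri(ws.g_X, U)
    pairs = build_pair_index(sa, job.thresholds)
    A, B, m = erpa_ab_matrices(sa, no_basis_blocks(g_no, sa.n_occupied), pairs)
    sol = solve_erpa(A, B, m, pairs, reference_state_index=2)
    pos, neg, amb = split_positive_negative(sol)
    tes = TwoElectronStates(ws.h_X("A"), ws.g_X, irreps=ws.labels,
                            enuc=ws.enuc("A"))
    gap_21 = tes.energies[2] - tes.energies[1]
    assert len(neg) >= 1
    # the single de-excitation (to the open-shell singlet) is recovered
    assert min(abs(sol.omega[k] + gap_21) for k in neg) < 1e-6


def test_degenerate_occupation_excited_state_is_diagnosed():
    """A singly-excited two-electron reference has half-filled (degenerate)
    occupations; its de-excitation pair is metric-singular, and the J-state
    response cannot reach the target state: the workflow raises a clear
    diagnostic rather than returning a silent zero."""
    mola, molb = h2_dimer_tshape(1.44, 1.44, 5.0)
    job = DimerJob(mola, molb, "6-31g**", "sa-cas(2,4,2)", "cas(2,4)",
                   state_a=1)
    from saptmc.erpa import ERPAInstability
    with pytest.raises((ERPAInstability, ValueError)):
        run_sapt(job)


def test_epsilon_corrections_from_lower_state_response_erpa():
    """ERPA route for the doubly-excited CAS reference: the ground-state
    (J=0) response supplies epsilon^(I->J); induction corrections are
    nonnegative and the dispersion correction lowers the energy."""
    from saptmc.second_pol import negative_transition_corrections
    from saptmc.workflow import _erpa_transition_set
    from saptmc.erpa import ERPASolution
    mola, molb = h2_dimer_tshape(1.44, 1.44, 5.0)
    job = DimerJob(mola, molb, "sto-3g", "sa-cas(2,2,3)", "cas(2,2)",
                   state_a=2)
    ws = MonomerWorkspace(job)
    ens = compute_monomer_ensemble(job, "A", ws)
    sb = compute_monomer_ensemble(job, "B", ws)[0]
    ints = build_integrals(ens[2], sb, ws)
    ts_b = _erpa_transition_set(sb, job, ints, ws, "B")
    ts_0 = _erpa_transition_set(ens[0], job, ints, ws, "A")
    from saptmc.second_pol import identify_target_root
    root = identify_target_root(ts_0._erpa_solution, 0, 2,
                                energy_gap=ens[2].energy - ens[0].energy)
    eps = negative_transition_corrections({0: ts_0}, {0: root}, ts_b, ints,
                                          "A")
    assert eps.eps_ind[0] >= -1e-14
    assert eps.eps_disp[0] < 0.0
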