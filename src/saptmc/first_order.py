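"""First-order SAPT: electrostatics and single-exchange (S^2) energy.

Two evaluation paths share the same contraction patterns:

* two-electron monomers: exact geminal algebra (GeminalPairContractions);
* general monomers: spin-summed 1-RDM / 2-RDM kernel contractions.  For
  singlet monomers every S^2 pattern reduces to the spin-summed densities
  with a universal factor 1/2 per exchange cycle; the kernel-oriented
  matrix of a (transition) density is the transpose of <bra|E_pq|ket>.

Both paths are validated against explicit antisymmetrizer tensor algebra.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .contractions import GeminalPairContractions, electrostatic_energy_frame
from .monomer import MonomerState
from .nointegrals import NOIntegrals


def electrostatic_energy(state_a: MonomerState, state_b: MonomerState,
                         ints: NOIntegrals) -> float:
    """E_elst^(1): Coulomb interaction of the unperturbed monomer densities."""
    return electrostatic_energy_frame(
        ints.gamma_a_X, ints.gamma_b_X, ints.vA_X, ints.vB_X,
        ints.ws.g_X, ints.V_AB_nuc)


@dataclass
class ExchangeIntermediates:
    """Cached pieces of the first-order S^2 evaluation reused at second order."""
    p1: float                  # <P1> over the unperturbed product
    e_elst: float
    v_p1: float


def _frame_geminal(state: MonomerState, U: np.ndarray) -> np.ndarray:
    if state.geminal is None:
        raise ValueError("monomer state carries no geminal (not two-electron?)")
    return U @ state.geminal @ U.T


def exchange_s2_energy(state_a: MonomerState, state_b: MonomerState,
                       ints: NOIntegrals,
                       return_intermediates: bool = False):
    """E_exch^(1)(S^2) = <V P1> - E_elst <P1> over the product state."""
    e_elst = electrostatic_energy(state_a, state_b, ints)
    if state_a.n_electrons == 2 and state_b.n_electrons == 2:
        gc = GeminalPairContractions(ints.ws.g_X, ints.vA_X, ints.vB_X,
                                     ints.V_AB_nuc)
        GA = _frame_geminal(state_a, ints.U_a)
        GB = _frame_geminal(state_b, ints.U_b)
        p1 = gc.p1(GA, GA, GB, GB)
        vp1 = gc.v_p1(GA, GA, GB, GB)
    else:
        p1, vp1 = _general_p1_vp1(state_a, state_b, ints)
    # antisymmetrizer: single transpositions enter with a fermionic minus
    e_exch = -(vp1 - e_elst * p1)
    if return_intermediates:
        return e_exch, ExchangeIntermediates(p1, e_elst, vp1)
    return e_exch


def _frame_rdm2(state: MonomerState, U: np.ndarray) -> np.ndarray:
    """Occupied-block spin-summed 2-RDM pushed to the frame basis."""
    D = state.get_rdm2()
    no = D.shape[0]
    Uo = U[:, :no]
    return np.einsum("pqrs,ap,bq,cr,ds->abcd", D, Uo, Uo, Uo, Uo,
                     optimize=True)


def _general_p1_vp1(state_a, state_b, ints: NOIntegrals):
    """General-monomer S^2 matrix elements from 1-/2-RDM kernels."""
    g = ints.ws.g_X
    wA, wB = ints.vA_X, ints.vB_X
    gA = ints.gamma_a_X       # diagonal states: kernel = density matrix
    gB = ints.gamma_b_X
    DA = _frame_rdm2(state_a, ints.U_a)
    DB = _frame_rdm2(state_b, ints.U_b)
    return general_p1_vp1_kernels(gA, DA, gB, DB, wA, wB, g, ints.V_AB_nuc)


def general_p1_vp1_kernels(gA, DA, gB, DB, wA, wB, g, vnn):
    """<P1> and <V P1> from kernel-oriented (transition) densities.

    gA/gB: kernel 1-density matrices; DA/DB: frame 2-RDM tensors with
    D[a,b,c,d] = <a+_a a+_c a_d a_b>; all in the common orthonormal frame.
    """
    p1 = 0.5 * float(np.trace(gA @ gB))
    t = vnn * p1
    # B's nuclear potential on A's electron labels
    t += 0.5 * float(np.trace(gA @ wB @ gB))
    t += 0.5 * float(np.einsum("abcd,ab,dc->", DA, gB, wB, optimize=True))
    # A's nuclear potential on B's electron labels
    t += 0.5 * float(np.trace(gA @ gB @ wA))
    t += 0.5 * float(np.einsum("abcd,ab,dc->", DB, gA, wA, optimize=True))
    # electron-electron: exchanged-exchanged
    t += 0.5 * float(np.einsum("bcda,ab,cd->", g, gA, gB, optimize=True))
    # exchanged(A label) - spectator(B)
    t += 0.5 * float(np.einsum("ab,apcd,bpcd->", gA, DB, g, optimize=True))
    # spectator(A) - exchanged(B label)
    t += 0.5 * float(np.einsum("ab,apcd,bpcd->", gB, DA, g, optimize=True))
    # spectator-spectator
    t += 0.5 * float(np.einsum("abcd,baef,cdef->", DA, DB, g, optimize=True))
    return p1, float(t)
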