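"""Second-order induction and dispersion energies.

All couplings are assembled from monomer transition sets: signed transition
energies plus transition one-particle densities (and, for two-electron
monomers, explicit excited-state geminals).  Transition sets come either
from ERPA solutions or from exact FCI state lists, so the same energy code
serves the production method and the benchmark oracle.

Excited monomers: sums run over positive transitions only; the missing
de-excitation contributions are restored by epsilon corrections computed
from ERPA solutions of the lower states (the transition J -> I, evaluated
in the J-state response where it appears as a positive excitation).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .erpa import ERPASolution, excited_geminals, transition_1rdms
from .monomer import MonomerState
from .nointegrals import NOIntegrals


@dataclass
class TransitionSet:
    """Transition quantities of one monomer, in the common frame.

    gamma[k] holds <ref|E_pq|k> (spin-summed); omega[k] = E_k - E_ref is
    signed.  For two-electron monomers ``geminals`` holds the (ket) state
    amplitudes and ``geminal0`` the reference amplitude.
    """
    omega: np.ndarray
    gamma: np.ndarray
    reference_index: int = 0
    geminals: np.ndarray | None = None
    geminal0: np.ndarray | None = None

    def positive(self, tol: float = 1e-8):
        return np.where(self.omega > tol)[0]

    def negative(self, tol: float = 1e-8):
        return np.where(self.omega < -tol)[0]

    def truncated(self, n_keep: int | None) -> "TransitionSet":
        """Subset with the lowest-|omega| transitions (energy-ordered input)."""
        if n_keep is None or n_keep >= len(self.omega):
            return self
        return TransitionSet(
            self.omega[:n_keep], self.gamma[:n_keep], self.reference_index,
            None if self.geminals is None else self.geminals[:n_keep],
            self.geminal0)


def transitions_from_erpa(sol: ERPASolution, state: MonomerState,
                          ints: NOIntegrals, which: str) -> TransitionSet:
    U = ints.U_a if which.upper() == "A" else ints.U_b
    g1 = transition_1rdms(sol)
    n = U.shape[0]
    gam = np.einsum("pa,kab,qb->kpq", U[:, :g1.shape[1]], g1,
                    U[:, :g1.shape[2]], optimize=True)
    gem = None
    gem0 = None
    if state.n_electrons == 2 and state.geminal is not None:
        gmats = excited_geminals(sol, state.geminal)
        gem = np.einsum("pa,kab,qb->kpq", U, gmats, U, optimize=True)
        gem0 = U @ state.geminal @ U.T
    return TransitionSet(sol.omega.copy(), gam, sol.reference_state_index,
                         gem, gem0)


def transitions_from_states(energies: np.ndarray, geminals_frame: np.ndarray,
                            reference_index: int,
                            n_states: int | None = None) -> TransitionSet:
    """Exact transition set for a two-electron monomer from FCI states."""
    nst = len(energies) if n_states is None else min(n_states, len(energies))
    ref = reference_index
    keep = [k for k in range(nst) if k != ref]
    G0 = geminals_frame[ref]
    omega = np.array([energies[k] - energies[ref] for k in keep])
    gamma = np.stack([2.0 * (G0 @ geminals_frame[k]) for k in keep])
    gems = np.stack([geminals_frame[k] for k in keep])
    return TransitionSet(omega, gamma, ref, gems, G0)


# ------------------------------------------------------------------ energies
def induction_couplings(ts: TransitionSet, omega_partner_X: np.ndarray):
    """t_k = <ref|Omega_partner|k> for every transition."""
    return np.einsum("kpq,pq->k", ts.gamma, omega_partner_X, optimize=True)


def induction_energy(ts_a: TransitionSet, ts_b: TransitionSet,
                     ints: NOIntegrals, tol: float = 1e-8):
    """E_ind+^(2) and its directional parts, positive transitions only."""
    omB_X = ints.embedding_potential_X("B")
    omA_X = ints.embedding_potential_X("A")
    pa = ts_a.positive(tol)
    pb = ts_b.positive(tol)
    ca = induction_couplings(ts_a, omB_X)
    cb = induction_couplings(ts_b, omA_X)
    e_ab = -float(np.sum(ca[pa] ** 2 / ts_a.omega[pa]))   # A <- B
    e_ba = -float(np.sum(cb[pb] ** 2 / ts_b.omega[pb]))   # B <- A
    return e_ab + e_ba, e_ab, e_ba


def dispersion_couplings(ts_a: TransitionSet, ts_b: TransitionSet,
                         ints: NOIntegrals) -> np.ndarray:
    """W[mu, nu] = sum gamma^mu (pq|rs) gamma^nu over the frame tensor."""
    g = ints.ws.g_X
    n = g.shape[0]
    Ga = ts_a.gamma.reshape(len(ts_a.omega), n * n)
    Gb = ts_b.gamma.reshape(len(ts_b.omega), n * n)
    return (Ga @ g.reshape(n * n, n * n)) @ Gb.T


def dispersion_energy(ts_a: TransitionSet, ts_b: TransitionSet,
                      ints: NOIntegrals, tol: float = 1e-8,
                      couplings: np.ndarray | None = None):
    """E_disp+^(2) over positive transitions of both monomers."""
    W = dispersion_couplings(ts_a, ts_b, ints) if couplings is None else couplings
    pa = ts_a.positive(tol)
    pb = ts_b.positive(tol)
    dena = ts_a.omega[pa][:, None] + ts_b.omega[pb][None, :]
    return -float(np.sum(W[np.ix_(pa, pb)] ** 2 / dena))


def split_positive_negative(sol: ERPASolution, tol: float = 1e-8):
    """Indices of excitation and de-excitation roots; flags ambiguous ones."""
    pos = sol.positive(tol)
    neg = sol.negative(tol)
    ambiguous = np.where(np.abs(sol.omega) <= tol)[0]
    return pos, neg, ambiguous


# -------------------------------------------------- negative transitions
@dataclass
class EpsilonCorrections:
    eps_disp: dict = field(default_factory=dict)   # J -> value
    eps_ind: dict = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)

    @property
    def disp_total(self) -> float:
        return float(sum(self.eps_disp.values()))

    @property
    def ind_total(self) -> float:
        return float(sum(self.eps_ind.values()))


def identify_target_root(sol_j: ERPASolution, j_index: int, i_index: int,
                         energy_gap: float | None = None,
                         gap_rtol: float = 0.5) -> int:
    """Root of the J-state ERPA approximating the J -> I transition.

    Selected by energy ordering of the positive roots (the (I-J)-th lowest);
    when the exact gap E_I - E_J is supplied, a sanity cross-check rejects a
    root deviating by more than ``gap_rtol`` relative.
    """
    pos = sol_j.positive()
    k = i_index - j_index - 1
    if k >= len(pos):
        raise ValueError(f"J={j_index} response has only {len(pos)} positive "
                         f"roots; cannot reach state I={i_index}")
    root = pos[k]
    if energy_gap is not None:
        w = sol_j.omega[root]
        if abs(w - energy_gap) > gap_rtol * abs(energy_gap):
            raise ValueError(
                f"could not identify the J={j_index} -> I={i_index} transition: "
                f"ERPA root {w:.6f} vs state gap {energy_gap:.6f}")
    return int(root)


def negative_transition_corrections(ts_lower: dict[int, TransitionSet],
                                    root_of: dict[int, int],
                                    ts_partner: TransitionSet,
                                    ints: NOIntegrals, excited_monomer: str,
                                    tol: float = 1e-8) -> EpsilonCorrections:
    """Epsilon corrections for monomer `excited_monomer` in state I.

    ``ts_lower[J]`` is the transition set of the lower-state (J) response of
    the excited monomer; ``root_of[J]`` indexes the J -> I transition in it.
    The partner monomer is in its ground state with transition set
    ``ts_partner``.
    """
    out = EpsilonCorrections()
    om_partner_X = ints.embedding_potential_X(
        "B" if excited_monomer.upper() == "A" else "A")
    for J, ts in ts_lower.items():
        k = root_of[J]
        w_IJ = ts.omega[k]            # omega_I^(A_J) > 0
        gam = ts.gamma[k]
        # induction: de-excitation contributes +|<gamma, Omega>|^2 / omega
        t = float(np.sum(gam * om_partner_X))
        out.eps_ind[J] = t ** 2 / w_IJ
        # dispersion: -sum_nu |W|^2 / (omega_nu^B - omega_I^(A_J))
        sub = TransitionSet(np.array([w_IJ]), gam[None])
        if excited_monomer.upper() == "A":
            W = dispersion_couplings(sub, ts_partner, ints)[0]
        else:
            W = dispersion_couplings(ts_partner, sub, ints)[:, 0]
        pb = ts_partner.positive(tol)
        den = ts_partner.omega[pb] - w_IJ
        if np.any(np.abs(den) < 1e-10):
            raise ValueError("degenerate monomer/partner transition energies "
                             "in a de-excitation denominator")
        out.eps_disp[J] = -float(np.sum(W[pb] ** 2 / den))
        out.provenance[J] = {"root": k, "omega": w_IJ}
    return out
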