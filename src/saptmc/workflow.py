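"""End-to-end SAPT drivers: component assembly, totals, hybrid models.

``run_sapt`` executes the full pipeline for a DimerJob:
monomer states -> interaction integrals -> linear response (ERPA, or exact
two-electron states for FCI monomers) -> all first- and second-order
components, including de-excitation corrections for excited monomers.
Supermolecular counterpoise-corrected HF/CASSCF/FCI energies, the delta_HF
correction and the CAS+DISP hybrid live here as well.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field

import numpy as np

from .core.ci import TwoElectronStates
from .core.ci4 import FCI4, product_guess
from .core.mcscf import casscf_general
from .core.mo import transform_eri, transform_matrix
from .core.scf import rhf
from .core.symmetry import mo_irrep_labels
from .erpa import (build_pair_index, erpa_ab_matrices, no_basis_blocks,
                   solve_erpa)
from .first_order import electrostatic_energy, exchange_s2_energy
from .monomer import (DimerJob, MethodSpec, MonomerState, MonomerWorkspace,
                      compute_monomer_ensemble)
from .nointegrals import NOIntegrals, build_integrals
from .second_exch import (exchange_dispersion_energy,
                          exchange_induction_energy)
from .second_pol import (EpsilonCorrections, TransitionSet,
                         dispersion_couplings, dispersion_energy,
                         identify_target_root, induction_energy,
                         negative_transition_corrections,
                         transitions_from_erpa, transitions_from_states)

HARTREE_TO_MILLI = 1e3


@dataclass
class SAPTComponents:
    e_elst: float
    e_exch: float
    e_ind_plus: float
    eps_ind_sum: float
    e_exch_ind: float
    e_disp_plus: float
    eps_disp_sum: float
    e_exch_disp: float
    e_ind_parts: tuple = (0.0, 0.0)
    e_exch_ind_parts: tuple = (0.0, 0.0)
    delta_hf: float | None = None
    delta_hf_included: bool = False
    epsilons: dict = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)

    @property
    def e_int(self) -> float:
        """Total through second order including de-excitation corrections."""
        e = (self.e_elst + self.e_exch + self.e_ind_plus + self.eps_ind_sum
             + self.e_exch_ind + self.e_disp_plus + self.eps_disp_sum
             + self.e_exch_disp)
        if self.delta_hf is not None and self.delta_hf_included:
            e += self.delta_hf
        return e

    @property
    def e_int_star(self) -> float:
        """Total without the negative-transition epsilon corrections."""
        return self.e_int - self.eps_ind_sum - self.eps_disp_sum

    def table(self, unit: float = HARTREE_TO_MILLI) -> dict:
        f = lambda x: round(x * unit, 3)
        return {
            "E_elst(1)": f(self.e_elst), "E_exch(1)": f(self.e_exch),
            "E_ind+(2)": f(self.e_ind_plus), "sum_eps_ind": f(self.eps_ind_sum),
            "E_exch-ind(2)": f(self.e_exch_ind),
            "E_disp+(2)": f(self.e_disp_plus),
            "sum_eps_disp": f(self.eps_disp_sum),
            "E_exch-disp(2)": f(self.e_exch_disp),
            "E_int_SAPT*": f(self.e_int_star), "E_int_SAPT": f(self.e_int),
        }

    def as_dict(self) -> dict:
        out = {k: getattr(self, k) for k in
               ("e_elst", "e_exch", "e_ind_plus", "eps_ind_sum", "e_exch_ind",
                "e_disp_plus", "eps_disp_sum", "e_exch_disp")}
        out["e_int"] = self.e_int
        out["e_int_star"] = self.e_int_star
        out["delta_hf"] = self.delta_hf
        out["metadata"] = self.metadata
        return out


def _erpa_transition_set(state: MonomerState, job: DimerJob,
                         ints: NOIntegrals, ws: MonomerWorkspace,
                         which: str) -> TransitionSet:
    U = ints.U_a if which.upper() == "A" else ints.U_b
    state.h_no = U.T @ ws.h_X(which) @ U
    nocc = state.n_occupied
    Uo = U[:, :nocc]
    blockA = transform_eri(ws.g_X, U, U, Uo, Uo)
    blockB = transform_eri(ws.g_X, Uo, U, Uo, U)
    pairs = build_pair_index(state, job.thresholds)
    A, B, metric = erpa_ab_matrices(state, (blockA, blockB), pairs)
    sol = solve_erpa(A, B, metric, pairs,
                     reference_state_index=state.state_index,
                     eig_positive_tol=job.thresholds.eig_positive_tol)
    ts = transitions_from_erpa(sol, state, ints, which)
    ts._erpa_solution = sol
    return ts


def _fci_transition_set(ws: MonomerWorkspace, which: str, ref_index: int,
                        ints: NOIntegrals, cap: int | None) -> TransitionSet:
    tes = TwoElectronStates(ws.h_X(which), ws.g_X, irreps=ws.labels,
                            enuc=ws.enuc(which))
    energies = tes.energies
    gems = tes.stacked_geminals()
    del tes   # free the per-state list before building transition stacks
    ts = transitions_from_states(energies, gems, ref_index, cap)
    del gems
    return ts


def run_sapt(job: DimerJob, workspace: MonomerWorkspace | None = None,
             transition_cap: int | None = None,
             exchange_transition_cap: int | None = 1200) -> SAPTComponents:
    """All SAPT(MC) components through second order for a dimer job.

    ``transition_cap`` limits the monomer transition sets entering the
    polarization sums (None = all states; FCI monomers only — ERPA sets are
    complete by construction).  ``exchange_transition_cap`` additionally
    truncates the sets entering the second-order exchange terms, whose
    amplitudes decay quickly with transition energy; exchange contributions
    are small and converge much faster than the dispersion sum."""
    t0 = time.time()
    ws = workspace or MonomerWorkspace(job)
    spec_a = MethodSpec.parse(job.method_a)
    spec_b = MethodSpec.parse(job.method_b)
    if job.state_a > 0 and job.state_b > 0:
        raise ValueError("at most one monomer may be electronically excited")
    ens_a = compute_monomer_ensemble(job, "A", ws)
    ens_b = compute_monomer_ensemble(job, "B", ws)
    st_a = ens_a[job.state_a]
    st_b = ens_b[job.state_b]
    ints = build_integrals(st_a, st_b, ws)

    if spec_a.kind == "fci":
        ts_a = _fci_transition_set(ws, "A", job.state_a, ints, transition_cap)
    else:
        ts_a = _erpa_transition_set(st_a, job, ints, ws, "A")
    if spec_b.kind == "fci":
        ts_b = _fci_transition_set(ws, "B", job.state_b, ints, transition_cap)
    else:
        ts_b = _erpa_transition_set(st_b, job, ints, ws, "B")

    e_elst = electrostatic_energy(st_a, st_b, ints)
    e_exch, inter = exchange_s2_energy(st_a, st_b, ints,
                                       return_intermediates=True)
    e_ind, e_ab, e_ba = induction_energy(ts_a, ts_b, ints)
    W = dispersion_couplings(ts_a, ts_b, ints)
    e_disp = dispersion_energy(ts_a, ts_b, ints, couplings=W)
    tx_a = ts_a.truncated(exchange_transition_cap)
    tx_b = ts_b.truncated(exchange_transition_cap)
    Wx = W[:len(tx_a.omega), :len(tx_b.omega)]
    exi, exi_ab, exi_ba = exchange_induction_energy(tx_a, tx_b, st_a, st_b,
                                                    ints, inter)
    exd = exchange_dispersion_energy(tx_a, tx_b, st_a, st_b, ints, inter,
                                     e_disp, couplings=Wx)

    eps = EpsilonCorrections()
    if job.negative_transitions and (job.state_a > 0 or job.state_b > 0):
        eps = _epsilon_corrections(job, ws, ints, ens_a, ens_b, ts_a, ts_b,
                                   spec_a, spec_b, transition_cap)

    comps = SAPTComponents(
        e_elst=e_elst, e_exch=e_exch, e_ind_plus=e_ind,
        eps_ind_sum=eps.ind_total, e_exch_ind=exi, e_disp_plus=e_disp,
        eps_disp_sum=eps.disp_total, e_exch_disp=exd,
        e_ind_parts=(e_ab, e_ba), e_exch_ind_parts=(exi_ab, exi_ba),
        epsilons={"ind": dict(eps.eps_ind), "disp": dict(eps.eps_disp)},
        metadata={
            "method_a": job.method_a, "method_b": job.method_b,
            "basis": job.basis, "state_a": job.state_a, "state_b": job.state_b,
            "n_transitions": (len(ts_a.omega), len(ts_b.omega)),
            "monomer_energies": (st_a.energy, st_b.energy),
            "negative_transitions": job.negative_transitions,
            "wall_time_s": round(time.time() - t0, 2),
        })
    return comps


def _epsilon_corrections(job, ws, ints, ens_a, ens_b, ts_a, ts_b,
                         spec_a, spec_b, cap):
    which = "A" if job.state_a > 0 else "B"
    I = job.state_a if which == "A" else job.state_b
    ens = ens_a if which == "A" else ens_b
    spec = spec_a if which == "A" else spec_b
    ts_partner = ts_b if which == "A" else ts_a
    lower, roots = {}, {}
    for J in range(I):
        st_j = ens[J]
        gap = ens[I].energy - st_j.energy
        if spec.kind == "fci":
            ts_j = _fci_transition_set(ws, which, J, ints, cap)
            roots[J] = _exact_root(ts_j, gap)
        else:
            ts_j = _erpa_transition_set(st_j, job, ints, ws, which)
            roots[J] = identify_target_root(ts_j._erpa_solution, J, I,
                                            energy_gap=gap)
        lower[J] = ts_j
    return negative_transition_corrections(lower, roots, ts_partner, ints,
                                           which)


def _exact_root(ts: TransitionSet, gap: float) -> int:
    return int(np.argmin(np.abs(ts.omega - gap)))


# ------------------------------------------------- supermolecular energies
def supermolecular_rhf_cp(job: DimerJob, workspace=None):
    """Counterpoise-corrected supermolecular RHF interaction energy."""
    ws = workspace or MonomerWorkspace(job)
    n = ws.kin_X.shape[0]
    eye = np.eye(n)
    h_d = ws.kin_X + ws._v["A"] + ws._v["B"]
    enuc_d = job.dimer_molecule().nuclear_repulsion()
    nel = ws.n_electrons("A") + ws.n_electrons("B")
    e_d, C, eps, dm = rhf(h_d, ws.g_X, eye, nel, enuc_d)
    e_a, _, _, _ = rhf(ws.h_X("A"), ws.g_X, eye, ws.n_electrons("A"),
                       ws.enuc("A"))
    e_b, _, _, _ = rhf(ws.h_X("B"), ws.g_X, eye, ws.n_electrons("B"),
                       ws.enuc("B"))
    return {"e_int": e_d - e_a - e_b, "e_dimer": e_d, "e_a": e_a, "e_b": e_b,
            "mo_coeffs": C, "mo_energies": eps}


def supermolecular_fci_cp(job: DimerJob, workspace=None, tol: float = 1e-5,
                          verbose: bool = False,
                          release_workspace: bool = False):
    """CP-corrected supermolecular FCI for a four-electron dimer (2e + 2e).

    ``release_workspace=True`` frees the workspace integral tensors once the
    MO transforms are done (the four-electron solve is the memory peak of
    the whole pipeline); the workspace cannot be reused afterwards.
    """
    ws = workspace or MonomerWorkspace(job)
    if ws.n_electrons("A") != 2 or ws.n_electrons("B") != 2:
        raise ValueError("supermolecular FCI supports two-electron monomers")
    hf = supermolecular_rhf_cp(job, ws)
    C_ao = ws.X @ hf["mo_coeffs"]
    C_pure, labels = mo_irrep_labels(ws.basis, ws.ints.S, C_ao,
                                     hf["mo_energies"])
    Cmo = ws.X.T @ ws.ints.S @ C_pure
    h_d = ws.kin_X + ws._v["A"] + ws._v["B"]
    h_mo = transform_matrix(h_d, Cmo)
    enuc_d = job.dimer_molecule().nuclear_repulsion()
    # CP monomer FCI (ground states, dimer basis) + product start vector
    tes_a = TwoElectronStates(ws.h_X("A"), ws.g_X, irreps=ws.labels,
                              enuc=ws.enuc("A"))
    e_a, GA0 = tes_a.energies[0], tes_a.geminals[0]
    del tes_a
    tes_b = TwoElectronStates(ws.h_X("B"), ws.g_X, irreps=ws.labels,
                              enuc=ws.enuc("B"))
    e_b, GB0 = tes_b.energies[0], tes_b.geminals[0]
    del tes_b
    ws.ints.eri = None if release_workspace else ws.ints.eri
    g_mo = transform_eri(ws.g_X, Cmo)
    if release_workspace:
        ws._g_X = None
    f4 = FCI4(h_mo, g_mo, irreps=labels, enuc=enuc_d)
    del g_mo
    GA = Cmo.T @ GA0 @ Cmo    # frame -> MO basis
    GB = Cmo.T @ GB0 @ Cmo
    guess = product_guess(f4, GA, GB)
    e_dimer, Cfci = f4.solve(guess=guess, tol=tol, verbose=verbose)
    return {"e_int": e_dimer - e_a - e_b, "e_dimer": e_dimer,
            "e_a": e_a, "e_b": e_b}


def supermolecular_cas_cp(job: DimerJob, dimer_active: tuple[int, int],
                          workspace=None, state: int = 0, n_avg: int = 1):
    """CP-corrected supermolecular CASSCF interaction energy.

    Monomer energies use each monomer's own method in the dimer basis;
    ``dimer_active`` = (n_electrons, n_orbitals) for the dimer CAS.
    """
    ws = workspace or MonomerWorkspace(job)
    hf = supermolecular_rhf_cp(job, ws)
    h_d = ws.kin_X + ws._v["A"] + ws._v["B"]
    enuc_d = job.dimer_molecule().nuclear_repulsion()
    nel = ws.n_electrons("A") + ws.n_electrons("B")
    ne_act, no_act = dimer_active
    ncore = (nel - ne_act) // 2
    res = casscf_general(h_d, ws.g_X, ncore, no_act, ne_act,
                         n_avg=max(n_avg, state + 1), enuc=enuc_d,
                         u0=hf["mo_coeffs"])
    e_dimer = res.state_energies[state]
    ens_a = compute_monomer_ensemble(job, "A", ws)
    ens_b = compute_monomer_ensemble(job, "B", ws)
    e_a = ens_a[job.state_a].energy
    e_b = ens_b[job.state_b].energy
    return {"e_int": e_dimer - e_a - e_b, "e_dimer": e_dimer,
            "e_a": e_a, "e_b": e_b, "converged": res.converged}


def delta_hf(job: DimerJob, workspace=None, sapt_total: float | None = None,
             threshold: float = 0.125):
    """delta_HF: supermolecular-HF estimate of higher-order induction.

    delta = E_int^HF - (E_elst + E_exch + E_ind + E_exch-ind) at the HF
    level (coupled).  The correction is flagged for inclusion when the
    induction share of the total interaction energy exceeds ``threshold``.
    """
    ws = workspace or MonomerWorkspace(job)
    hf_job = DimerJob(job.geometry_a, job.geometry_b, job.basis, "hf", "hf",
                      thresholds=job.thresholds)
    comps = run_sapt(hf_job, ws)
    e_hf = supermolecular_rhf_cp(hf_job, ws)["e_int"]
    delta = e_hf - (comps.e_elst + comps.e_exch + comps.e_ind_plus
                    + comps.e_exch_ind)
    total = sapt_total if sapt_total is not None else comps.e_int
    ratio = abs((comps.e_ind_plus + comps.e_exch_ind) / total) \
        if total else 0.0
    return {"delta_hf": delta, "include": bool(ratio > threshold),
            "ratio": ratio, "e_int_hf": e_hf}


def cas_plus_disp(job: DimerJob, dimer_active: tuple[int, int],
                  workspace=None, sapt: SAPTComponents | None = None):
    """CAS+DISP hybrid: supermolecular CASSCF plus SAPT dispersion.

    E = E_int^CAS(CP) + E_disp+ + sum_eps_disp + E_exch-disp; for excited
    states only the dispersion de-excitation corrections enter.
    """
    ws = workspace or MonomerWorkspace(job)
    state = max(job.state_a, job.state_b)
    sup = supermolecular_cas_cp(job, dimer_active, ws, state=state)
    comps = sapt if sapt is not None else run_sapt(job, ws)
    e = sup["e_int"] + comps.e_disp_plus + comps.eps_disp_sum \
        + comps.e_exch_disp
    return {"e_cas_disp": e, "e_int_cas": sup["e_int"],
            "e_disp_total": comps.e_disp_plus + comps.eps_disp_sum
            + comps.e_exch_disp, "components": comps}


def scan(job_factory, grid, runner=run_sapt):
    """Run a job per grid point; failures are isolated per point."""
    rows = []
    for point in grid:
        row = {"point": point}
        try:
            job = job_factory(point)
            comps = runner(job)
            row.update(comps.as_dict() if hasattr(comps, "as_dict") else comps)
            row["ok"] = True
        except Exception as exc:   # per-point isolation by design
            row["ok"] = False
            row["error"] = f"{type(exc).__name__}: {exc}"
        rows.append(row)
    return rows
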