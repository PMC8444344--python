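"""Second-order exchange-induction and exchange-dispersion (S^2).

Both follow the single-exchange combination

    E_exch-pol = <0|(V - E_elst)(P1 - <P1>)|Psi^(1)>
               = sum_amp c [ <V P1>_t - E_elst <P1>_t ] - <P1>_00 E_pol

with |Psi^(1)> the first-order induction or dispersion wave function.  For
the induction case the amplitude sum is linear, so it collapses into a
single "response geminal" (or response density) and one master-contraction
evaluation per direction.  The dispersion case keeps the double transition
sum; each S^2 pattern then becomes a matrix product
L(mu) . G~ . R(nu) over reordered frame Coulomb tensors, evaluated with
one large GEMM per pattern.

Two-electron monomers use exact transition geminals; larger monomers use a
product-factorized transition 2-RDM (exact in the single-determinant limit).
"""

from __future__ import annotations

import numpy as np

from .contractions import GeminalPairContractions
from .first_order import ExchangeIntermediates, general_p1_vp1_kernels
from .monomer import MonomerState
from .nointegrals import NOIntegrals
from .second_pol import (TransitionSet, dispersion_couplings,
                         induction_couplings)


def _frame_geminal(state: MonomerState, U: np.ndarray) -> np.ndarray:
    return U @ state.geminal @ U.T


def _gc(ints: NOIntegrals) -> GeminalPairContractions:
    return GeminalPairContractions(ints.ws.g_X, ints.vA_X, ints.vB_X,
                                   ints.V_AB_nuc)


def exchange_induction_energy(ts_a: TransitionSet, ts_b: TransitionSet,
                              state_a: MonomerState, state_b: MonomerState,
                              ints: NOIntegrals,
                              inter: ExchangeIntermediates,
                              tol: float = 1e-8):
    """E_exch-ind^(2)(S^2), coupled; returns (total, A<-B, B<-A)."""
    omB = ints.embedding_potential_X("B")
    omA = ints.embedding_potential_X("A")
    parts = []
    for ts, om_X, which in ((ts_a, omB, "A"), (ts_b, omA, "B")):
        pos = ts.positive(tol)
        v0 = induction_couplings(ts, om_X)[pos]
        c = -v0 / ts.omega[pos]
        e_ind_dir = -float(np.sum(v0 ** 2 / ts.omega[pos]))
        state = state_a if which == "A" else state_b
        partner = state_b if which == "A" else state_a
        if state.n_electrons == 2 and partner.n_electrons == 2 \
                and ts.geminals is not None:
            gem_resp = np.einsum("k,kpq->pq", c, ts.geminals[pos])
            gc = _gc(ints)
            GA0 = _frame_geminal(state_a, ints.U_a)
            GB0 = _frame_geminal(state_b, ints.U_b)
            if which == "A":
                vp1 = gc.v_p1(GA0, gem_resp, GB0, GB0)
                p1t = gc.p1(GA0, gem_resp, GB0, GB0)
            else:
                vp1 = gc.v_p1(GA0, GA0, GB0, gem_resp)
                p1t = gc.p1(GA0, GA0, GB0, gem_resp)
        else:
            vp1, p1t = _general_response_vp1(ts, c, pos, state, partner,
                                             ints, which)
        # fermionic minus of the single-transposition antisymmetrizer term
        parts.append(-(vp1 - inter.e_elst * p1t - inter.p1 * e_ind_dir))
    return parts[0] + parts[1], parts[0], parts[1]


def _factorized_trdm2(gam_tr, gam0):
    """Transition 2-RDM from the product factorization (determinant limit).

    Operator-convention storage D[a,b,c,d] = <bra|a+_a a+_c a_d a_b|ket>
    linearized around the closed-shell product form
    D = gamma x gamma - 1/2 gamma ^ gamma; both inputs are operator-
    oriented matrices <a+_x a_y>."""
    return (np.einsum("ab,cd->abcd", gam_tr, gam0)
            + np.einsum("ab,cd->abcd", gam0, gam_tr)
            - 0.5 * np.einsum("ad,cb->abcd", gam_tr, gam0)
            - 0.5 * np.einsum("ad,cb->abcd", gam0, gam_tr))


def _general_response_vp1(ts, c, pos, state, partner, ints, which):
    """Exchange-induction matrix elements via factorized transition 2-RDMs."""
    # operator-oriented response transition density (sum over amplitudes)
    gam_tr = np.einsum("k,kpq->pq", c, ts.gamma[pos])
    gam_resp = gam_tr.T      # kernel orientation for the one-body slot
    if which == "A":
        gam0_exc = ints.gamma_a_X
        gam0_part = ints.gamma_b_X
    else:
        gam0_exc = ints.gamma_b_X
        gam0_part = ints.gamma_a_X
    D_resp = _factorized_trdm2(gam_tr, gam0_exc)
    from .first_order import _frame_rdm2
    D_part = _frame_rdm2(partner, ints.U_b if which == "A" else ints.U_a)
    if which == "A":
        p1, vp1 = general_p1_vp1_kernels(gam_resp, D_resp, gam0_part, D_part,
                                         ints.vA_X, ints.vB_X, ints.ws.g_X,
                                         ints.V_AB_nuc)
    else:
        p1, vp1 = general_p1_vp1_kernels(gam0_part, D_part, gam_resp, D_resp,
                                         ints.vA_X, ints.vB_X, ints.ws.g_X,
                                         ints.V_AB_nuc)
    return vp1, p1


def _rowspace(G: np.ndarray, cutoff: float = 1e-7) -> np.ndarray:
    """Orthonormal basis of the numerically relevant column space of a
    symmetric geminal (natural-expansion coefficients above cutoff)."""
    c, U = np.linalg.eigh(G)
    keep = np.abs(c) > cutoff
    if not keep.any():
        keep[np.argmax(np.abs(c))] = True
    return U[:, keep]


def projected_coulomb(g: np.ndarray, UP: np.ndarray, UQ: np.ndarray) -> np.ndarray:
    """g1[a,q,b,s] = sum_pr g[p,q,r,s] UP[p,a] UQ[r,b] — the only Coulomb
    tensor the exchange-dispersion patterns need, since every transition
    intermediate has its first index in the reference geminal's column
    space."""
    n = g.shape[0]
    rA = UP.shape[1]
    x = UP.T @ g.reshape(n, -1)                     # (a, q r s)
    x = x.reshape(rA, n, n, n).transpose(0, 1, 3, 2).reshape(-1, n)  # (aqs, r)
    x = x @ UQ                                      # (a q s, b)
    return np.ascontiguousarray(
        x.reshape(rA, n, n, UQ.shape[1]).transpose(0, 1, 3, 2))


def exchange_dispersion_energy(ts_a: TransitionSet, ts_b: TransitionSet,
                               state_a: MonomerState, state_b: MonomerState,
                               ints: NOIntegrals,
                               inter: ExchangeIntermediates,
                               e_disp: float,
                               couplings: np.ndarray | None = None,
                               tol: float = 1e-8,
                               rank_cutoff: float = 1e-5) -> float:
    """E_exch-disp^(2)(S^2), coupled, for two-electron monomers."""
    if ts_a.geminals is None or ts_b.geminals is None:
        raise NotImplementedError(
            "exchange-dispersion requires explicit transition geminals "
            "(two-electron monomers)")
    g = ints.ws.g_X
    n = g.shape[0]
    pa = ts_a.positive(tol)
    pb = ts_b.positive(tol)
    W = dispersion_couplings(ts_a, ts_b, ints) if couplings is None else couplings
    W = W[np.ix_(pa, pb)]
    camp = -W / (ts_a.omega[pa][:, None] + ts_b.omega[pb][None, :])
    P = _frame_geminal(state_a, ints.U_a)
    Q = _frame_geminal(state_b, ints.U_b)
    GAs = ts_a.geminals[pa]
    GBs = ts_b.geminals[pb]
    na, nb = len(pa), len(pb)
    UP = _rowspace(P, rank_cutoff)
    UQ = _rowspace(Q, rank_cutoff)
    rA, rB = UP.shape[1], UQ.shape[1]
    g1 = projected_coulomb(g, UP, UQ)               # (rA, n, rB, n)

    # stacked per-transition matrices (projected where possible)
    PG = np.einsum("pa,kab->kpb", UP.T @ P, GAs, optimize=True)   # (k, rA, n)
    QG = np.einsum("pa,kab->kpb", UQ.T @ Q, GBs, optimize=True)   # (k, rB, n)
    PGQ = np.einsum("kpa,ab->kpb", PG, Q @ UQ, optimize=True)     # (k, rA, rB)
    GQ = np.einsum("kab,bq->kaq", GAs, Q @ UQ, optimize=True)     # (k, n, rB)
    PGB = np.einsum("pa,kab->kpb", UP.T @ P, GBs, optimize=True)  # (k, rA, n)
    QGP = np.einsum("kpa,ab->kpb", QG, P @ UP, optimize=True)     # (k, rB, rA)

    # pattern 1 (both exchanged): sum g[pqrs] (PG)_ps (QG)_rq
    #   = sum g1[a,q,b,s] PG[a,s] QG[b,q]
    gm = np.ascontiguousarray(g1.transpose(0, 3, 2, 1)).reshape(rA * n, rB * n)
    M = (PG.reshape(na, -1) @ gm) @ QG.reshape(nb, -1).T
    del gm
    # pattern 2 (exch A - spect B): sum g[pqrs] (PGQ)_pr (G_nu)_qs
    gm = np.ascontiguousarray(g1.transpose(0, 2, 1, 3)).reshape(rA * rB, n * n)
    M += (PGQ.reshape(na, -1) @ gm) @ GBs.reshape(nb, -1).T
    del gm
    # pattern 3 (spect A - exch B): sum g[yvzu] (QGP)_zy (G_mu)_uv
    #   = sum g1[a,v,b,u] G_mu[u,v] QGP[b,a]
    gm = np.ascontiguousarray(g1.transpose(3, 1, 0, 2)).reshape(n * n, rA * rB)
    M += (GAs.reshape(na, -1) @ gm) @ QGP.transpose(0, 2, 1).reshape(nb, -1).T
    del gm
    # pattern 4 (spect-spect): sum g[yvwn] (P G_nu)_yn (G_mu Q)_vw
    #   = sum g1[a,v,b,n] PGB[a,n] GQ[v,b]
    gm = np.ascontiguousarray(g1.transpose(1, 2, 0, 3)).reshape(n * rB, rA * n)
    M += (GQ.reshape(na, -1) @ gm) @ PGB.reshape(nb, -1).T
    del gm, g1
    # nuclear + one-body traces: tr(P G_mu [.] Q G_nu [.]) per (mu, nu);
    # left factors live in col(P), right factors are pulled back by UP
    wA, wB = ints.vA_X, ints.vB_X
    vnn = ints.V_AB_nuc
    QG_full = np.einsum("ab,kbc->kac", Q, GBs, optimize=True)     # (l, n, n)

    def pairtrace(Lk, Rk):
        # Lk: (k, rA, n); Rk: (l, n, rA)
        return np.einsum("kas,lsa->kl", Lk, Rk, optimize=True)

    QGU = QG_full @ UP
    trP1 = pairtrace(PG, QGU)
    M += vnn * trP1
    M += pairtrace(PG, np.einsum("kab,bc->kac", QG_full, wB @ UP,
                                 optimize=True))
    M += pairtrace(np.einsum("ab,kbc->kac", UP.T @ P @ wB, GAs,
                             optimize=True), QGU)
    M += pairtrace(np.einsum("kab,bc->kac", PG, wA, optimize=True), QGU)
    M += pairtrace(PG, np.einsum("ab,kbc->kac", Q @ wA, GBs,
                                 optimize=True) @ UP)
    vp1 = 2.0 * M
    p1t = 2.0 * trP1
    e = float(np.sum(camp * (vp1 - inter.e_elst * p1t))) - inter.p1 * e_disp
    return -e   # fermionic minus of the single-transposition term
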