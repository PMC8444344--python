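"""CASSCF orbital optimization.

Two routes:

* ``casscf_two_electron`` — exact variable-projection optimizer for
  two-electron systems.  The energy of CAS(2,m) is the lowest eigenvalue of
  the full pair-space Hamiltonian projected onto the symmetric pair
  functions of an m-dimensional orbital subspace; only the subspace enters,
  so the optimization runs over active-virtual rotations with an analytic
  (Hellmann-Feynman) gradient.  State averaging weights the lowest roots.

* ``casscf_general`` — small-scale CASSCF for arbitrary electron counts
  (dense determinant CI in the active space, generalized-Fock orbital
  gradient, L-BFGS over all nonredundant rotations).  Used for dimer
  CASSCF and state-averaged test systems; cost is dominated by one
  integral transformation per energy evaluation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg as sla
import scipy.optimize as sopt

from .ci import FCISolver, TwoElectronStates, _pair_block
from .mo import transform_eri


@dataclass
class CASSCFResult:
    energy: float                 # weighted (SA) or state energy
    state_energies: np.ndarray    # CI roots in the optimized active space
    mo_coeffs: np.ndarray         # full orbital set, active block first
    n_active: int
    n_core: int
    ci_vectors: np.ndarray        # active-space CI vectors (columns)
    converged: bool
    grad_norm: float


# ------------------------------------------------------------ two-electron
def _pair_embed(Uact: np.ndarray) -> np.ndarray:
    """Embedding of the active symmetric pair basis into the full pair basis.

    Full pair basis: symmetrized |pq>, p<=q over n orbitals; active basis the
    same over the columns of Uact.  Returns matrix P with columns = active
    pair functions expressed in the full pair basis.
    """
    n, m = Uact.shape
    iu_f = np.triu_indices(n)
    iu_a = np.triu_indices(m)
    cols = []
    for k, l in zip(*iu_a):
        G = np.outer(Uact[:, k], Uact[:, l])
        G = 0.5 * (G + G.T) * (2.0 if k != l else 1.0)  # normalized geminal
        if k != l:
            G /= np.sqrt(2.0)
        v = np.where(iu_f[0] == iu_f[1], G[iu_f], np.sqrt(2.0) * G[iu_f])
        cols.append(v)
    return np.array(cols).T


def _unpack_pair(v: np.ndarray, n: int) -> np.ndarray:
    """Pair-basis vector -> symmetric geminal matrix (Frobenius-normalized)."""
    iu = np.triu_indices(n)
    G = np.zeros((n, n))
    off = iu[0] != iu[1]
    G[iu[0][off], iu[1][off]] = v[off] / np.sqrt(2.0)
    G[iu[1][off], iu[0][off]] = v[off] / np.sqrt(2.0)
    G[iu[0][~off], iu[1][~off]] = v[~off]
    return G


def casscf_two_electron(h: np.ndarray, g: np.ndarray, n_active: int,
                        n_avg: int = 1, weights=None, enuc: float = 0.0,
                        u0: np.ndarray | None = None, gtol: float = 1e-7,
                        maxiter: int = 400, irreps: np.ndarray | None = None):
    """CAS(2, n_active) for a two-electron system over an orthonormal basis.

    Returns a CASSCFResult whose mo_coeffs express the optimized orbitals in
    the input basis (active block first, then the orthogonal complement).
    ``irreps`` (abelian labels) only speed up the initial-guess
    diagonalization; the optimization itself is label-free.
    """
    n = h.shape[0]
    m = n_active
    if weights is None:
        weights = np.full(n_avg, 1.0 / n_avg)
    weights = np.asarray(weights, float)
    # full pair-space Hamiltonian, built once
    iu = np.triu_indices(n)
    Hp = _pair_block(h, g, iu[0], iu[1])
    if u0 is None:
        # natural orbitals of the full two-electron ground state
        # (irrep-blocked diagonalization when labels are available)
        G0 = _ground_geminal(h, g, Hp, iu, irreps)
        occ, nos = np.linalg.eigh(G0 @ G0)
        u0 = nos[:, ::-1]
    nvar = m * (n - m)

    def unpack_kappa(x):
        K = np.zeros((n, n))
        blk = x.reshape(m, n - m)
        K[:m, m:] = blk
        K[m:, :m] = -blk.T
        return K

    state = {}

    def eval_eg(x):
        K = unpack_kappa(x)
        expK = sla.expm(K)
        U = u0 @ expK
        Uact = U[:, :m]
        P = _pair_embed(Uact)
        HpP = Hp @ P
        Hact = P.T @ HpP
        wact, Vact = np.linalg.eigh(Hact)
        E = float(weights @ wact[:n_avg])
        # gradient wrt Uact, averaged over states (Hellmann-Feynman)
        GU = np.zeros((n, m))
        for i in range(n_avg):
            gv = P @ Vact[:, i]
            Mg = _unpack_pair(Hp @ gv, n)
            A = _unpack_pair_small(Vact[:, i], m)
            GU += weights[i] * 4.0 * (Mg @ Uact @ A)
        W = np.zeros((n, n))
        W[:, :m] = u0.T @ GU
        dK = sla.expm_frechet(K.T, W, compute_expm=False)
        dK = dK - dK.T  # project onto antisymmetric variations
        grad = dK[:m, m:].ravel()
        state["U"] = U
        state["roots"] = wact
        state["vecs"] = Vact
        return E, grad

    res = sopt.minimize(eval_eg, np.zeros(nvar), jac=True, method="L-BFGS-B",
                        options={"maxiter": maxiter, "gtol": gtol,
                                 "ftol": 1e-14})
    E, grad = eval_eg(res.x)
    U = state["U"]
    nkeep = max(n_avg, 1)
    return CASSCFResult(
        energy=E + enuc,
        state_energies=state["roots"][: m * (m + 1) // 2] + enuc,
        mo_coeffs=U,
        n_active=m,
        n_core=0,
        ci_vectors=state["vecs"],
        converged=bool(res.success or np.linalg.norm(grad) < 1e-5),
        grad_norm=float(np.linalg.norm(grad)),
    )


def _unpack_pair_small(v: np.ndarray, m: int) -> np.ndarray:
    return _unpack_pair(v, m)


def _ground_geminal(h, g, Hp, iu, irreps):
    """Ground-state geminal of the full pair problem (blocked if labeled)."""
    n = h.shape[0]
    if irreps is None:
        w, V = np.linalg.eigh(Hp)
        return _unpack_pair(V[:, 0], n)
    labels = np.asarray(irreps, np.int64)
    pair_ir = np.bitwise_xor(labels[iu[0]], labels[iu[1]])
    best = (np.inf, None, None)
    for ir in np.unique(pair_ir):
        sel = np.where(pair_ir == ir)[0]
        w, V = np.linalg.eigh(Hp[np.ix_(sel, sel)])
        if w[0] < best[0]:
            best = (w[0], V[:, 0], sel)
    vec = np.zeros(len(iu[0]))
    vec[best[2]] = best[1]
    return _unpack_pair(vec, n)


# ---------------------------------------------------------------- general
def _core_quantities(h, g, ncore):
    """Core energy and core Fock contribution to the active one-electron part."""
    if ncore == 0:
        return 0.0, h
    c = slice(0, ncore)
    ecore = 2.0 * np.trace(h[c, c]) \
        + 2.0 * np.einsum("iijj->", g[c, c, c, c]) \
        - np.einsum("ijji->", g[c, c, c, c])
    veff = 2.0 * np.einsum("pqii->pq", g[:, :, c, c]) \
        - np.einsum("piiq->pq", g[:, c, c, :])
    return float(ecore), h + veff


def casscf_general(h: np.ndarray, g: np.ndarray, n_core: int, n_active: int,
                   nelec_active: int, n_avg: int = 1, weights=None,
                   enuc: float = 0.0, u0: np.ndarray | None = None,
                   gtol: float = 1e-6, maxiter: int = 300):
    """CASSCF over an orthonormal basis; orbitals ordered core|active|virtual."""
    n = h.shape[0]
    na = n_active
    nc = n_core
    if weights is None:
        weights = np.full(n_avg, 1.0 / n_avg)
    weights = np.asarray(weights, float)
    if u0 is None:
        u0 = np.eye(n)
    # nonredundant rotations: core-active, core-virtual, active-virtual
    pairs = [(i, j) for i in range(nc) for j in range(nc, n)] + \
            [(i, j) for i in range(nc, nc + na) for j in range(nc + na, n)]
    nvar = len(pairs)
    pi = np.array([p for p, _ in pairs], int)
    pj = np.array([q for _, q in pairs], int)
    state = {}

    def eval_eg(x):
        K = np.zeros((n, n))
        K[pi, pj] = x
        K[pj, pi] = -x
        U = u0 @ sla.expm(K)
        hm = U.T @ h @ U
        gm = transform_eri(g, U)  # full transform: small bases only
        ecore, heff = _core_quantities(hm, gm, nc)
        act = slice(nc, nc + na)
        solver = FCISolver(heff[act, act], gm[act, act, act, act], nelec_active)
        wact, Vact = solver.solve_singlets(max(n_avg, 1))
        E = float(weights @ (wact[:n_avg] + ecore))
        # state-averaged RDMs
        d1 = np.zeros((na, na))
        d2 = np.zeros((na, na, na, na))
        for i in range(n_avg):
            v = Vact[:, i]
            d1 += weights[i] * solver.trdm1(v, v)
            d2 += weights[i] * solver.trdm2(v, v)
        # generalized Fock: F_pq = sum_r D_qr heff... assembled blockwise
        F = np.zeros((n, n))
        csl = slice(0, nc)
        # inactive Fock (doubly occupied core) and active Fock
        fI = hm + 2.0 * np.einsum("pqii->pq", gm[:, :, csl, csl]) \
            - np.einsum("piiq->pq", gm[:, csl, csl, :])
        fA = np.einsum("pqts,ts->pq", gm[:, :, act, act], d1) \
            - 0.5 * np.einsum("ptsq,ts->pq", gm[:, act, act, :], d1)
        F[csl, :] = 2.0 * (fI + fA)[:, csl].T
        F[act, :] = (d1 @ fI[:, act].T) \
            + np.einsum("tuvw,quvw->tq", d2, gm[:, act, act, act])
        gamma = 2.0 * (F.T - F)  # local rotation gradient at the current U
        # chain through the global exponential parametrization
        A = sla.expm_frechet(K.T, sla.expm(K) @ (0.5 * gamma), compute_expm=False)
        A = A - A.T
        state["U"] = U
        state["roots"] = wact + ecore
        state["vecs"] = Vact
        state["d1"] = d1
        return E, A[pi, pj]

    res = sopt.minimize(eval_eg, np.zeros(nvar), jac=True, method="L-BFGS-B",
                        options={"maxiter": maxiter, "gtol": gtol,
                                 "ftol": 1e-14})
    E, grad = eval_eg(res.x)
    return CASSCFResult(
        energy=E + enuc,
        state_energies=state["roots"] + enuc,
        mo_coeffs=state["U"],
        n_active=na,
        n_core=nc,
        ci_vectors=state["vecs"],
        converged=bool(res.success or np.linalg.norm(grad) < 1e-4),
        grad_norm=float(np.linalg.norm(grad)),
    )
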