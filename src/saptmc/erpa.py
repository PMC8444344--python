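"""Extended random phase approximation for a single monomer.

The ERPA eigenproblem is the equation-of-motion ansatz with single
(de-)excitation operators over a correlated reference:

    [ A  B ] [X_nu]          [ N   0 ] [X_nu]
    [ B  A ] [Y_nu] = omega  [ 0  -N ] [Y_nu]

with A, B double-commutator expectation values assembled exclusively from
the one- and two-particle reduced density matrices of the reference state,
and a diagonal metric N built from occupation-number differences.  For a
single-determinant reference the equations reduce to standard RPA/TDHF.

Orbital pairs (p, q) run over p "less occupied" than q with q inactive or
active and p active or virtual; degenerate active pairs are discarded by a
relative occupation-gap filter (they would make the metric singular).
Transition one-particle densities follow from the eigenvectors and the
metric; for two-electron monomers the full excited-state geminal is also
reconstructed, which makes every two-particle transition quantity exact at
the ERPA-amplitude level.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg as sla

from .monomer import MonomerState, ThresholdSet


class ERPAInstability(RuntimeError):
    """Complex ERPA eigenvalues: the reference is unstable in linear response."""


@dataclass
class PairIndex:
    pairs: np.ndarray          # (npair, 2) orbital index pairs (p, q)
    metric: np.ndarray         # n_q - n_p per pair (per-spin occupations)
    discarded: np.ndarray      # pairs removed by the degeneracy filter

    def __len__(self):
        return len(self.pairs)


def build_pair_index(state: MonomerState, thresholds: ThresholdSet | None = None,
                     degeneracy_threshold: float | None = None) -> PairIndex:
    """Orbital-pair list for the ERPA problem of one monomer state.

    Pairs (p, q): q in s1 (inactive) or s2 (active), p in s2 or s3 with
    p > q in the descending-occupation ordering; no pair has both indices
    in s3 or both in s1.  Active-active pairs with a relative occupation
    gap below the method's degeneracy threshold are discarded.
    """
    thr = thresholds or ThresholdSet()
    if degeneracy_threshold is None:
        degeneracy_threshold = (thr.pair_degeneracy_gvb
                                if state.method.lower().startswith("gvb")
                                else thr.pair_degeneracy_cas)
    occ = state.occ
    s1, s2, s3 = set(state.s1.tolist()), set(state.s2.tolist()), set(state.s3.tolist())
    pairs, metric, dropped = [], [], []
    norb = len(occ)
    for q in sorted(s1 | s2):
        for p in range(q + 1, norb):
            if p in s1:
                continue
            if p in s3 and q in s3:
                continue
            if p in s2 and q in s2:
                denom = max(occ[q], occ[p])
                if denom <= 0 or abs(occ[q] - occ[p]) / denom < degeneracy_threshold:
                    dropped.append((p, q))
                    continue
            m = occ[q] - occ[p]
            if abs(m) < thr.metric_zero_tol:
                dropped.append((p, q))
                continue
            pairs.append((p, q))
            metric.append(m)
    return PairIndex(np.array(pairs, int).reshape(-1, 2),
                     np.array(metric),
                     np.array(dropped, int).reshape(-1, 2))


def no_basis_blocks(g_full: np.ndarray, nocc: int):
    """The two master integral blocks the ERPA builder needs.

    blockA[p,q,u,v] = (pq|uv) with u,v occupied;
    blockB[u,p,v,q] = (up|vq) with u,v occupied.
    For large bases these are produced by partial AO->NO transforms instead
    (see sapt drivers); this helper slices a full NO-basis tensor (tests,
    small systems).
    """
    o = np.arange(nocc)
    blockA = np.ascontiguousarray(g_full[:, :, :nocc, :nocc])
    blockB = np.ascontiguousarray(g_full[np.ix_(o, np.arange(g_full.shape[1]),
                                                o, np.arange(g_full.shape[3]))])
    return blockA, blockB


def erpa_ab_matrices(state: MonomerState, blocks, pair_index: PairIndex):
    """ERPA matrices A, B and the diagonal metric for one monomer state.

    ``blocks = (blockA, blockB)`` are the NO-basis integral blocks from
    :func:`no_basis_blocks`.  A and B are assembled from the general
    double-commutator element

        M[(ab),(rs)] = <[E_ab, [H, E_rs]]>

    evaluated with the diagonal 1-RDM and the occupied-block 2-RDM:
    A[(pq),(rs)] = M[(qp),(rs)], B[(pq),(rs)] = M[(qp),(sr)].
    """
    blockA, blockB = blocks
    occ = state.occ
    n = len(occ)
    nocc = state.n_occupied
    D = state.get_rdm2()
    h = _effective_h(state, None)

    g_XXoo = blockA                                    # (qr|uv)
    g_oXoo = blockA[:nocc]                             # (tr|uv), t occ
    g_oXXo = blockB.transpose(0, 1, 3, 2)              # [t,r,b,v] = (tr|bv)
    g_oXoX = blockB                                    # [t,r,u,a] = (tr|ua)
    g_sTuv = blockA.transpose(0, 1, 2, 3)[:, :nocc]    # [s,t,u,v] = (st|uv)
    g_sTbV = blockB.transpose(1, 0, 3, 2)              # [s,t,b,v] = (st|bv)
    g_sTuA = blockB.transpose(1, 0, 2, 3)              # [s,t,u,a] = (st|ua)

    # A3 pieces (from  sum_tuv g_truv <[E_ab, e_{ts,uv}]> )
    K1 = np.einsum("asuv,bruv->asbr", D, g_XXoo, optimize=True)
    T2 = np.einsum("tsav,trbv->sarb", D, g_oXXo, optimize=True)
    Y = np.einsum("truv,tbuv->rb", g_oXoo, D, optimize=True)
    T4 = np.einsum("tsub,trua->sbra", D, g_oXoX, optimize=True)
    # A4 pieces (from -sum_tuv g_stuv <[E_ab, e_{rt,uv}]>)
    X1 = np.einsum("stuv,atuv->sa", g_sTuv, D, optimize=True)
    T6 = np.einsum("rtav,stbv->rasb", D, g_sTbV, optimize=True)
    K7 = np.einsum("rbuv,sauv->rbsa", D, g_XXoo, optimize=True)
    T8 = np.einsum("rtub,stua->rbsa", D, g_sTuA, optimize=True)

    def element_block(left, right):
        """M[(ab),(rs)] for arrays of left pairs (a,b) and right pairs (r,s)."""
        a = left[:, 0][:, None]
        b = left[:, 1][:, None]
        r = right[:, 0][None, :]
        s = right[:, 1][None, :]
        na_ = occ[left[:, 0]][:, None]
        nb_ = occ[left[:, 1]][:, None]
        M = 2.0 * h[b, r] * (a == s) * (na_ - nb_) \
            + 2.0 * (b == r) * h[s, a] * (nb_ - na_)
        # occupied-index masks (contributions vanish when index not occupied)
        am = (left[:, 0] < nocc)
        bm = (left[:, 1] < nocc)
        rm = (right[:, 0] < nocc)
        sm = (right[:, 1] < nocc)
        ac = np.where(am, left[:, 0], 0)[:, None]
        bc = np.where(bm, left[:, 1], 0)[:, None]
        rc = np.where(rm, right[:, 0], 0)[None, :]
        sc = np.where(sm, right[:, 1], 0)[None, :]
        amr = am[:, None]
        bmr = bm[:, None]
        rmr = rm[None, :]
        smr = sm[None, :]
        # A3: + K1[a,s;b,r] + T2[s,a;r,b] - delta_sa Y[r,b] - T4[s,b;r,a]
        M = M + np.where(amr & smr, K1[ac, sc, b, r], 0.0)
        M = M + np.where(amr & smr, T2[sc, ac, r, b], 0.0)
        M = M - np.where((a == s) & bmr, Y[r, bc], 0.0)
        M = M - np.where(smr & bmr, T4[sc, bc, r, a], 0.0)
        # A4: - delta_br X1[s,a] - T6[r,a;s,b] + K7[r,b;s,a] + T8[r,b;s,a]
        M = M - np.where((b == r) & amr, X1[s, ac], 0.0)
        M = M - np.where(rmr & amr, T6[rc, ac, s, b], 0.0)
        M = M + np.where(rmr & bmr, K7[rc, bc, s, a], 0.0)
        M = M + np.where(rmr & bmr, T8[rc, bc, s, a], 0.0)
        return M

    pr = pair_index.pairs
    left = pr[:, ::-1]          # (q, p): the daggered excitation operator
    A = element_block(left, pr)
    B = element_block(left, pr[:, ::-1])
    # true metric <[E_qp, E_pq]> = 2 (n_q - n_p) (spin-summed)
    metric = 2.0 * pair_index.metric
    return A, B, metric


def _effective_h(state: MonomerState, g_no: np.ndarray) -> np.ndarray:
    """One-electron matrix consistent with the stored monomer energy.

    The monomer Hamiltonian in the NO basis: the caller supplies h via the
    state workspace; here we reconstruct it from the cached attribute set by
    the SAPT driver (kept on the state to avoid replumbing integrals).
    """
    h = getattr(state, "h_no", None)
    if h is None:
        raise ValueError("state.h_no not set: attach the one-electron matrix "
                         "in the NO basis before building ERPA matrices")
    return h


@dataclass
class ERPASolution:
    pairs: PairIndex
    omega: np.ndarray          # signed transition energies, sorted by |omega|
    X: np.ndarray              # (npair, nroot)
    Y: np.ndarray
    metric: np.ndarray
    reference_state_index: int = 0

    @property
    def n_roots(self):
        return len(self.omega)

    def positive(self, tol: float = 1e-8) -> np.ndarray:
        return np.where(self.omega > tol)[0]

    def negative(self, tol: float = 1e-8) -> np.ndarray:
        return np.where(self.omega < -tol)[0]

    def save(self, path):
        """HDF5 dump (lower-state solutions are reused by the
        negative-transition workflow)."""
        import h5py
        with h5py.File(path, "w") as f:
            f["pairs"] = self.pairs.pairs
            f["pair_metric"] = self.pairs.metric
            f["discarded"] = self.pairs.discarded
            f["omega"] = self.omega
            f["X"] = self.X
            f["Y"] = self.Y
            f["metric"] = self.metric
            f.attrs["reference_state_index"] = self.reference_state_index

    @classmethod
    def load(cls, path) -> "ERPASolution":
        import h5py
        with h5py.File(path, "r") as f:
            pairs = PairIndex(f["pairs"][...], f["pair_metric"][...],
                              f["discarded"][...])
            return cls(pairs, f["omega"][...], f["X"][...], f["Y"][...],
                       f["metric"][...],
                       int(f.attrs["reference_state_index"]))


def solve_erpa(A: np.ndarray, B: np.ndarray, metric: np.ndarray,
               pair_index: PairIndex, reference_state_index: int = 0,
               eig_positive_tol: float = 1e-8,
               instability_tol: float = 1e-6) -> ERPASolution:
    """Solve the ERPA generalized eigenproblem.

    Ground-state references use the symmetric reduced form
    (A-B)(A+B)|Z> = omega^2 N^2 |Z| when A±B are positive definite;
    otherwise (excited references) a dense generalized solver on the full
    2n x 2n problem is used.  Complex eigenvalues raise ERPAInstability.
    """
    npair = len(metric)
    if npair == 0:
        return ERPASolution(pair_index, np.zeros(0), np.zeros((0, 0)),
                            np.zeros((0, 0)), metric, reference_state_index)
    Ap = 0.5 * (A + A.T)
    Bp = 0.5 * (B + B.T)
    if reference_state_index == 0:
        # symmetric reduced form: with u = X+Y, N~ = N^{-1/2},
        #   [N~(A-B)N~][N~(A+B)N~] y = omega^2 y,  u = N~ y.
        # Requires A+B (and A-B) positive definite: true for stable
        # ground-state references.
        try:
            nh = 1.0 / np.sqrt(metric)
            M1 = nh[:, None] * (Ap - Bp) * nh[None, :]
            M2 = nh[:, None] * (Ap + Bp) * nh[None, :]
            L = np.linalg.cholesky(0.5 * (M2 + M2.T))
            K = L.T @ M1 @ L
            w2, Z = np.linalg.eigh(0.5 * (K + K.T))
            if w2[0] < -instability_tol:
                raise np.linalg.LinAlgError
            w2 = np.clip(w2, 0.0, None)
            om = np.sqrt(w2)
            Yz = sla.solve_triangular(L.T, Z, lower=False)
            XpY = nh[:, None] * Yz
            X = np.empty_like(XpY)
            Y = np.empty_like(XpY)
            for k in range(len(om)):
                if om[k] > eig_positive_tol:
                    XmY = (Ap + Bp) @ XpY[:, k] / om[k] / metric
                else:
                    XmY = XpY[:, k]
                X[:, k] = 0.5 * (XpY[:, k] + XmY)
                Y[:, k] = 0.5 * (XpY[:, k] - XmY)
            return _normalize(ERPASolution(pair_index, om, X, Y, metric,
                                           reference_state_index))
        except np.linalg.LinAlgError:
            pass
    return solve_erpa_dense(Ap, Bp, metric, pair_index, reference_state_index,
                            eig_positive_tol, instability_tol)


def solve_erpa_dense(A, B, metric, pair_index, reference_state_index=0,
                     eig_positive_tol=1e-8, instability_tol=1e-6):
    """Dense generalized eigensolver on the full block problem."""
    npair = len(metric)
    H = np.block([[A, B], [B, A]])
    S = np.zeros((2 * npair, 2 * npair))
    S[:npair, :npair] = np.diag(metric)
    S[npair:, npair:] = -np.diag(metric)
    w, V = sla.eig(H, S)
    if np.abs(w.imag).max() > instability_tol * max(1.0, np.abs(w.real).max()):
        bad = np.abs(w.imag).max()
        raise ERPAInstability(
            f"complex ERPA eigenvalues (max imag {bad:.2e}) for reference "
            f"state {reference_state_index}; the underlying wave function is "
            "unstable in linear response — choose a different state or "
            "active space")
    w = w.real
    V = V.real
    # each physical root appears twice (omega, -omega paired solutions);
    # keep one representative per eigenvector family via metric signature
    X = V[:npair]
    Y = V[npair:]
    nrm = np.einsum("p,pk,pk->k", metric, X, X) \
        - np.einsum("p,pk,pk->k", metric, Y, Y)
    keep = nrm > 1e-10
    sol = ERPASolution(pair_index, w[keep], X[:, keep], Y[:, keep], metric,
                       reference_state_index)
    return _normalize(sol)


def _normalize(sol: ERPASolution) -> ERPASolution:
    """Metric normalization, deterministic ordering and sign fixing."""
    m = sol.metric
    nrm = np.einsum("p,pk,pk->k", m, sol.X, sol.X) \
        - np.einsum("p,pk,pk->k", m, sol.Y, sol.Y)
    good = nrm > 1e-12
    X = sol.X[:, good] / np.sqrt(nrm[good])
    Y = sol.Y[:, good] / np.sqrt(nrm[good])
    om = sol.omega[good]
    # order by |omega| then sign, deterministic tie-break on first pair index
    order = np.lexsort((np.argmax(np.abs(X), axis=0), np.sign(om), np.abs(om)))
    X, Y, om = X[:, order], Y[:, order], om[order]
    # phase: largest-magnitude X component positive
    for k in range(X.shape[1]):
        j = np.argmax(np.abs(X[:, k]))
        if X[j, k] < 0:
            X[:, k] *= -1
            Y[:, k] *= -1
    return ERPASolution(sol.pairs, om, X, Y, sol.metric,
                        sol.reference_state_index)


def transition_1rdms(sol: ERPASolution, roots=None) -> np.ndarray:
    """Spin-summed 1-TRDMs gamma^nu_ab = <0|E_ab|nu> stacked as (nroot, n, n).

    With the EOM ansatz and the metric m = <[E_qp, E_pq]> = 2(n_q - n_p),
    <0|E_qp|nu> = m X_pq and <0|E_pq|nu> = -m Y_pq for each pair (p, q).
    """
    if roots is None:
        roots = np.arange(sol.n_roots)
    n = int(sol.pairs.pairs.max()) + 1 if len(sol.pairs.pairs) else 0
    out = np.zeros((len(roots), n, n))
    p = sol.pairs.pairs[:, 0]
    q = sol.pairs.pairs[:, 1]
    m = sol.metric
    for i, k in enumerate(roots):
        out[i][q, p] = m * sol.X[:, k]
        out[i][p, q] = -m * sol.Y[:, k]
    return out


def excited_geminals(sol: ERPASolution, geminal0: np.ndarray,
                     roots=None) -> np.ndarray:
    """Excited-state geminals O+_nu |0> for a two-electron monomer.

    E_pq acting on a geminal C gives  e_pq C + C e_pq^T  (replace orbital q
    by p in either slot), so each ERPA root maps to an explicit two-electron
    state; all two-particle transition quantities then follow exactly from
    the amplitudes.  Geminals are returned unnormalized (norm approaches 1
    in the exact-response limit).
    """
    if roots is None:
        roots = np.arange(sol.n_roots)
    n = geminal0.shape[0]
    out = np.zeros((len(roots), n, n))
    p = sol.pairs.pairs[:, 0]
    q = sol.pairs.pairs[:, 1]
    for i, k in enumerate(roots):
        M = np.zeros((n, n))
        # operator sum_pq (X E_pq + Y E_qp): build its orbital matrix
        np.add.at(M, (p, q), sol.X[:, k])
        np.add.at(M, (q, p), sol.Y[:, k])
        G = M @ geminal0 + geminal0 @ M.T
        out[i] = G
    return out
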