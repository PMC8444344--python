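"""Determinant configuration interaction.

Two solvers live here:

* a general full-CI over a small orbital space (bitmask determinants,
  dense Hamiltonian) used for CASSCF active spaces and as an exact
  operator-algebra oracle in tests;
* a two-electron singlet solver over the full orbital space, where states
  are symmetric geminal matrices C with ``Psi = sum_pq C_pq |p_alpha q_beta>``
  and all transition density matrices are closed-form matrix products.
"""

from __future__ import annotations

import itertools

import numpy as np
from numba import njit


# ---------------------------------------------------------------- strings
def strings(norb: int, nelec: int) -> np.ndarray:
    """All nelec-in-norb occupation bitmasks, lexicographic."""
    out = []
    for occ in itertools.combinations(range(norb), nelec):
        m = 0
        for o in occ:
            m |= 1 << o
        out.append(m)
    return np.array(out, np.int64)


@njit(cache=True)
def _popcount(x):
    n = 0
    while x:
        x &= x - 1
        n += 1
    return n


@njit(cache=True)
def _occ_list(mask, norb, out):
    n = 0
    for p in range(norb):
        if mask >> p & 1:
            out[n] = p
            n += 1
    return n


@njit(cache=True)
def _sign_excite(mask, p, q):
    """Sign and new mask for a+_p a_q acting on a string; 0 if invalid."""
    if not (mask >> q & 1):
        return 0, mask
    m1 = mask & ~(1 << q)
    if m1 >> p & 1:
        return 0, mask
    m2 = m1 | (1 << p)
    # parity of occupied orbitals between positions
    lo, hi = (p, q) if p < q else (q, p)
    count = 0
    for r in range(lo + 1, hi):
        if m1 >> r & 1:
            count += 1
    sign = -1 if count % 2 else 1
    return sign, m2


@njit(cache=True)
def _build_h(stra, strb, norb, h, g):
    """Dense Hamiltonian over determinants (alpha string x beta string).

    g is (pq|rs) in chemists' notation.  Determinant convention: alpha
    creation operators first (ordered ascending), then beta.
    """
    na, nb = len(stra), len(strb)
    ndet = na * nb
    H = np.zeros((ndet, ndet))
    occ = np.empty(norb, np.int64)
    # effective one-electron term including the same-spin two-electron diag
    # handled via explicit Slater-Condon below
    idx_a = {}
    for i in range(na):
        idx_a[stra[i]] = i
    idx_b = {}
    for i in range(nb):
        idx_b[strb[i]] = i
    for ia in range(na):
        ma = stra[ia]
        noa = _occ_list(ma, norb, occ)
        oa = occ[:noa].copy()
        for ib in range(nb):
            mb = strb[ib]
            nob = _occ_list(mb, norb, occ)
            ob = occ[:nob].copy()
            I = ia * nb + ib
            # diagonal
            e = 0.0
            for x in oa:
                e += h[x, x]
            for x in ob:
                e += h[x, x]
            for xi in range(noa):
                for xj in range(xi + 1, noa):
                    x, y = oa[xi], oa[xj]
                    e += g[x, x, y, y] - g[x, y, y, x]
            for xi in range(nob):
                for xj in range(xi + 1, nob):
                    x, y = ob[xi], ob[xj]
                    e += g[x, x, y, y] - g[x, y, y, x]
            for x in oa:
                for y in ob:
                    e += g[x, x, y, y]
            H[I, I] = e
            # alpha singles (Slater-Condon row generation; each J once)
            for q in oa:
                for p in range(norb):
                    if ma >> p & 1:
                        continue
                    s1, m2 = _sign_excite(ma, p, q)
                    J = idx_a[m2] * nb + ib
                    e = h[p, q]
                    for x in oa:
                        if x != q:
                            e += g[p, q, x, x] - g[p, x, x, q]
                    for y in ob:
                        e += g[p, q, y, y]
                    H[I, J] += s1 * e
            # beta singles
            for q in ob:
                for p in range(norb):
                    if mb >> p & 1:
                        continue
                    s1, m2 = _sign_excite(mb, p, q)
                    J = ia * nb + idx_b[m2]
                    e = h[p, q]
                    for x in ob:
                        if x != q:
                            e += g[p, q, x, x] - g[p, x, x, q]
                    for y in oa:
                        e += g[p, q, y, y]
                    H[I, J] += s1 * e
            # alpha-alpha doubles: remove q<q2, add p<p2 (all outside ma)
            for qi in range(noa):
                for qj in range(qi + 1, noa):
                    q, q2 = oa[qi], oa[qj]
                    for p in range(norb):
                        if ma >> p & 1:
                            continue
                        for p2 in range(p + 1, norb):
                            if ma >> p2 & 1:
                                continue
                            s1, m2 = _sign_excite(ma, p, q)
                            s2, m3 = _sign_excite(m2, p2, q2)
                            J = idx_a[m3] * nb + ib
                            H[I, J] += s1 * s2 * (g[p, q, p2, q2] - g[p, q2, p2, q])
            # beta-beta doubles
            for qi in range(nob):
                for qj in range(qi + 1, nob):
                    q, q2 = ob[qi], ob[qj]
                    for p in range(norb):
                        if mb >> p & 1:
                            continue
                        for p2 in range(p + 1, norb):
                            if mb >> p2 & 1:
                                continue
                            s1, m2 = _sign_excite(mb, p, q)
                            s2, m3 = _sign_excite(m2, p2, q2)
                            J = ia * nb + idx_b[m3]
                            H[I, J] += s1 * s2 * (g[p, q, p2, q2] - g[p, q2, p2, q])
            # alpha-beta doubles
            for q in oa:
                for p in range(norb):
                    if ma >> p & 1:
                        continue
                    s1, m2 = _sign_excite(ma, p, q)
                    for q2 in ob:
                        for p2 in range(norb):
                            if mb >> p2 & 1:
                                continue
                            s2, m3 = _sign_excite(mb, p2, q2)
                            J = idx_a[m2] * nb + idx_b[m3]
                            H[I, J] += s1 * s2 * g[p, q, p2, q2]
    return H


class FCISolver:
    """Dense FCI in a small orbital space (both spins share orbitals)."""

    def __init__(self, h: np.ndarray, g: np.ndarray, nelec: int, norb: int | None = None):
        self.norb = norb if norb is not None else h.shape[0]
        if nelec % 2:
            raise ValueError("only closed-shell electron counts supported")
        self.na = self.nb = nelec // 2
        self.stra = strings(self.norb, self.na)
        self.strb = self.stra
        self.h = np.ascontiguousarray(h[: self.norb, : self.norb])
        self.g = np.ascontiguousarray(g[: self.norb, : self.norb,
                                        : self.norb, : self.norb])
        self.H = _build_h(self.stra, self.strb, self.norb, self.h, self.g)
        self.ndet = self.H.shape[0]
        self._eig = None

    def solve(self, nroots: int | None = None):
        if self._eig is None:
            self._eig = np.linalg.eigh(self.H)
        w, V = self._eig
        if nroots is None:
            return w, V
        return w[:nroots], V[:, :nroots]

    def singlet_indices(self, thresh: float = 0.5) -> np.ndarray:
        """Roots whose CI matrix is symmetric under alpha<->beta interchange.

        For two active electrons this selects exactly the singlets; for more
        electrons it keeps even-S roots (adequate for the low states of the
        closed-shell systems handled here).
        """
        w, V = self.solve()
        na, nb = len(self.stra), len(self.strb)
        out = []
        for k in range(len(w)):
            c = V[:, k].reshape(na, nb)
            sym = np.sum(c * c.T)
            if sym > thresh:
                out.append(k)
        return np.array(out, int)

    def solve_singlets(self, nroots: int):
        w, V = self.solve()
        idx = self.singlet_indices()[:nroots]
        return w[idx], V[:, idx]

    # --- operator algebra ------------------------------------------------
    def apply_epq(self, vec: np.ndarray, p: int, q: int) -> np.ndarray:
        """Spin-summed singlet excitation operator E_pq acting on a CI vector."""
        na, nb = len(self.stra), len(self.strb)
        out = np.zeros_like(vec)
        idx_a = {int(m): i for i, m in enumerate(self.stra)}
        v = vec.reshape(na, nb)
        o = out.reshape(na, nb)
        for ia, ma in enumerate(self.stra):
            s, m2 = _sign_excite(int(ma), p, q)
            if s:
                o[idx_a[int(m2)], :] += s * v[ia, :]
        for ib, mb in enumerate(self.strb):
            s, m2 = _sign_excite(int(mb), p, q)
            if s:
                o[:, idx_a[int(m2)]] += s * v[:, ib]
        return out

    def trdm1(self, bra: np.ndarray, ket: np.ndarray) -> np.ndarray:
        """Spin-summed <bra|E_pq|ket> for all p, q."""
        n = self.norb
        out = np.empty((n, n))
        for p in range(n):
            for q in range(n):
                out[p, q] = bra @ self.apply_epq(ket, p, q)
        return out

    def trdm2(self, bra: np.ndarray, ket: np.ndarray) -> np.ndarray:
        """Spin-summed two-particle (transition) density in chemists' pairing.

        D[p,q,r,s] = sum_{sigma,tau} <bra| a+_{p sig} a+_{r tau} a_{s tau}
        a_{q sig} |ket> = <E_pq E_rs> - delta_qr <E_ps>.
        """
        n = self.norb
        evecs = {}
        for r in range(n):
            for s in range(n):
                evecs[r, s] = self.apply_epq(ket, r, s)
        d1 = self.trdm1(bra, ket)
        out = np.empty((n, n, n, n))
        for p in range(n):
            for q in range(n):
                left = self.apply_epq(bra, q, p)  # E_pq^dagger |bra>
                for r in range(n):
                    for s in range(n):
                        out[p, q, r, s] = left @ evecs[r, s]
                        if q == r:
                            out[p, q, r, s] -= d1[p, s]
        return out


# ------------------------------------------------ two-electron singlets
class TwoElectronStates:
    """All singlet eigenstates of a two-electron Hamiltonian.

    States are geminal matrices: ``Psi_nu = sum_pq C[nu]_pq |p_a q_b>`` with
    C symmetric and Frobenius-normalized.  Optional irrep labels enable
    symmetry-blocked diagonalization; state irreps are reported.
    """

    def __init__(self, h: np.ndarray, g: np.ndarray, irreps: np.ndarray | None = None,
                 enuc: float = 0.0):
        m = h.shape[0]
        self.norb = m
        self.enuc = enuc
        iu = np.triu_indices(m)
        self.pair_idx = iu
        npair = len(iu[0])
        if irreps is None:
            irreps = np.zeros(m, np.int64)
        self.irreps = np.asarray(irreps, np.int64)
        pair_ir = np.bitwise_xor(self.irreps[iu[0]], self.irreps[iu[1]])
        energies = []
        gems = []
        state_ir = []
        for ir in np.unique(pair_ir):
            sel = np.where(pair_ir == ir)[0]
            Hb = _pair_block(h, g, iu[0][sel], iu[1][sel])
            w, V = np.linalg.eigh(Hb)
            for k in range(len(w)):
                energies.append(w[k])
                C = np.zeros((m, m))
                ps, qs = iu[0][sel], iu[1][sel]
                amp = V[:, k].copy()
                # basis |pq>_sym = (|pq>+|qp>)/sqrt2 for p<q, |pp> for p=q
                off = ps != qs
                C[ps[off], qs[off]] = amp[off] / np.sqrt(2.0)
                C[qs[off], ps[off]] = amp[off] / np.sqrt(2.0)
                on = ~off
                C[ps[on], qs[on]] = amp[on]
                gems.append(C)
                state_ir.append(ir)
        order = np.argsort(np.array(energies), kind="stable")
        self.energies = np.array(energies)[order] + enuc
        self.geminals = [gems[i] for i in order]
        self.state_irreps = np.array(state_ir, np.int64)[order]

    @property
    def n_states(self) -> int:
        return len(self.energies)

    def trdm1(self, mu: int, nu: int) -> np.ndarray:
        """Spin-summed transition 1-RDM <mu|E_pq|nu> = 2 (C_mu C_nu)_pq."""
        return 2.0 * self.geminals[mu] @ self.geminals[nu]

    def stacked_geminals(self, nmax: int | None = None) -> np.ndarray:
        n = self.n_states if nmax is None else min(nmax, self.n_states)
        return np.stack([self.geminals[k] for k in range(n)])


def _pair_block(h, g, ps, qs):
    """Singlet two-electron Hamiltonian over symmetrized pair functions."""
    npair = len(ps)
    # raw product-basis matrix elements H[(pq),(rs)] = h_pr d_qs + d_pr h_qs + (pr|qs)
    p, q = ps[:, None], qs[:, None]
    r, s = ps[None, :], qs[None, :]
    direct = h[p, r] * (q == s) + (p == r) * h[q, s] + g[p, r, q, s]
    exch = h[p, s] * (q == r) + (p == s) * h[q, r] + g[p, s, q, r]
    offb = (ps != qs)[:, None]
    offk = (ps != qs)[None, :]
    fac_b = np.where(offb, 1.0 / np.sqrt(2.0), 0.5)
    fac_k = np.where(offk, 1.0 / np.sqrt(2.0), 0.5)
    # <sym_bra|H|sym_ket>: each symmetrized function (|pq>+|qp>)*fac
    return (direct + exch) * (2.0 * fac_b * fac_k)
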