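"""Full CI for four electrons (2 alpha + 2 beta) in a large orbital space.

The CI coefficient is held as a matrix over alpha-pair x beta-pair strings.
The sigma vector splits into same-spin parts (dense two-electron pair
Hamiltonian applied from the left/right) and an alpha-beta Coulomb part
evaluated as one large matrix product over reordered four-index tensors,
optionally block-diagonalized by abelian irrep labels.  A Davidson solver
with spin symmetrization computes the lowest singlet root.
"""

from __future__ import annotations

import numpy as np


class FCI4:
    def __init__(self, h: np.ndarray, g: np.ndarray, irreps: np.ndarray | None = None,
                 enuc: float = 0.0):
        n = h.shape[0]
        self.norb = n
        self.enuc = enuc
        ii, jj = np.triu_indices(n, 1)
        self.pi, self.pj = ii, jj
        self.nstr = len(ii)
        # same-spin pair Hamiltonian  <ij|H|kl>  (i<j, k<l antisymmetric pairs)
        i, j = ii[:, None], jj[:, None]
        k, l = ii[None, :], jj[None, :]
        H2 = h[i, k] * (j == l) + h[j, l] * (i == k) \
            - h[i, l] * (j == k) - h[j, k] * (i == l) \
            + g[i, k, j, l] - g[i, l, j, k]
        self.H2 = H2
        # diagonal Coulomb between spins for the preconditioner
        Jmat = np.einsum("ppqq->pq", g)
        P = np.zeros((self.nstr, n))
        P[np.arange(self.nstr), ii] = 1.0
        P[np.arange(self.nstr), jj] = 1.0
        self.diag = np.diag(H2)[:, None] + np.diag(H2)[None, :] \
            + P @ Jmat @ P.T
        # ordered-pair bookkeeping for the alpha-beta contraction
        if irreps is None:
            irreps = np.zeros(n, np.int64)
        self.irreps = np.asarray(irreps, np.int64)
        self._prepare_blocks(g)
        self._Tr = None  # persistent contraction buffers
        self._M = None

    def _prepare_blocks(self, g):
        n = self.norb
        lab = self.irreps
        prod = np.bitwise_xor.outer(lab, lab).ravel()  # label of ordered pair (a,c)
        self.block_rows = [np.where(prod == b)[0] for b in np.unique(prod)]
        # V2[(i,k),(q,s)] = (iq|ks), kept blockwise (block-diagonal by symmetry)
        V2 = np.ascontiguousarray(g.transpose(0, 2, 1, 3)).reshape(n * n, n * n)
        self.V2_blocks = [np.ascontiguousarray(V2[rows][:, rows])
                          for rows in self.block_rows]
        del V2

    def sigma(self, C: np.ndarray) -> np.ndarray:
        n = self.norb
        out = self.H2 @ C + C @ self.H2.T
        ii, jj = self.pi, self.pj
        ra, ca = ii[:, None], jj[:, None]      # alpha pair (i, j)
        rb, cb = ii[None, :], jj[None, :]      # beta pair (k, l)
        # scatter the antisymmetric extension directly in (q, s, j, l) layout:
        # Tr[(q,s),(j,l)] = Ct[q j, s l]
        if self._Tr is None:
            self._Tr = np.zeros((n, n, n, n))
            self._M = np.empty((n * n, n * n))
        T4 = self._Tr
        T4.reshape(-1)[:] = 0.0
        T4[ra, rb, ca, cb] = C
        T4[ca, rb, ra, cb] = -C
        T4[ra, cb, ca, rb] = -C
        T4[ca, cb, ra, rb] = C
        Tr = T4.reshape(n * n, n * n)
        M = self._M
        for rows, Vb in zip(self.block_rows, self.V2_blocks):
            M[rows] = Vb @ Tr[rows]
        M4 = M.reshape(n, n, n, n)             # axes (i, k, j, l), view
        out += M4[ra, rb, ca, cb]
        out -= M4[ca, rb, ra, cb]
        out -= M4[ra, cb, ca, rb]
        out += M4[ca, cb, ra, rb]
        return out

    def solve(self, guess: np.ndarray | None = None, tol: float = 1e-6,
              max_iter: int = 60, verbose: bool = False):
        """Davidson for the lowest singlet root.  Returns (energy, C)."""
        ns = self.nstr
        if guess is None:
            imin = np.unravel_index(np.argmin(self.diag), self.diag.shape)
            C = np.zeros((ns, ns))
            C[imin] = 1.0
        else:
            C = guess.copy()
        C = 0.5 * (C + C.T)
        C /= np.linalg.norm(C)
        vecs, sigmas = [], []
        theta = None
        x = C
        for it in range(max_iter):
            # orthogonalize x against subspace
            for v in vecs:
                x = x - v * np.sum(v * x)
            nx = np.linalg.norm(x)
            if nx < 1e-12:
                break
            x /= nx
            vecs.append(x)
            sigmas.append(self.sigma(x))
            m = len(vecs)
            Hs = np.empty((m, m))
            for a in range(m):
                for b in range(m):
                    Hs[a, b] = np.sum(vecs[a] * sigmas[b])
            Hs = 0.5 * (Hs + Hs.T)
            w, V = np.linalg.eigh(Hs)
            theta = w[0]
            cvec = V[:, 0]
            resid = sum(c * s for c, s in zip(cvec, sigmas)) \
                - theta * sum(c * v for c, v in zip(cvec, vecs))
            rn = np.linalg.norm(resid)
            if verbose:
                print(f"  davidson it {it}: E={theta + self.enuc:.10f} |r|={rn:.2e}")
            if rn < tol:
                break
            denom = self.diag - theta
            denom = np.where(np.abs(denom) < 1e-6, 1e-6, denom)
            x = resid / denom
            x = 0.5 * (x + x.T)
            if m >= 8:  # collapse subspace (memory: vectors are large)
                best = sum(c * v for c, v in zip(cvec, vecs))
                best /= np.linalg.norm(best)
                vecs, sigmas = [best], [self.sigma(best)]
        Cfin = sum(c * v for c, v in zip(cvec, vecs))
        Cfin /= np.linalg.norm(Cfin)
        return theta + self.enuc, Cfin


def product_guess(fci: FCI4, gem_a: np.ndarray, gem_b: np.ndarray) -> np.ndarray:
    """Davidson start vector from a product of two singlet geminals.

    Both geminals must be expressed over the same orbital basis as the FCI
    (e.g. dimer molecular orbitals).  The (2a,2b) determinant coefficients
    of  |G_A> x |G_B>  are assembled and compacted onto i<j, k<l pairs.
    """
    T = -np.einsum("pq,rs->prqs", gem_a, gem_b)   # alpha pair (p,r), beta (q,s)
    ii, jj = fci.pi, fci.pj
    ra, ca = ii[:, None], jj[:, None]
    rb, cb = ii[None, :], jj[None, :]
    C = T[ra, ca, rb, cb] - T[ca, ra, rb, cb] - T[ra, ca, cb, rb] + T[ca, ra, cb, rb]
    n = np.linalg.norm(C)
    if n < 1e-12:
        raise ValueError("product guess vanishes (check geminal bases)")
    return C / n
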