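"""Single-exchange (S^2) matrix elements over monomer-product states.

Master formulas.  For the single-exchange operator P1, a matrix element
between products of singlet states factorizes into spatial contractions of
monomer (transition) densities with a universal spin factor of 1/2 per
exchanged pair; with both monomers two-electron singlets represented by
geminal amplitude matrices P (bra A), A (ket A), Q (bra B), B (ket B), all
expressed in one orthonormal frame, the exchanged-pair pattern gives

    <PQ| P1 |AB>          = 2 tr(PA QB)
    <PQ| sum_i w(r_i) P1 |AB>  (w on A's electrons)
                          = 2 [ tr(PA QB w) + tr(P w A QB) ]
    <PQ| sum_j w(r_j) P1 |AB>  (w on B's electrons)
                          = 2 [ tr(PA w QB) + tr(PA Q w B) ]
    <PQ| sum_ij v(r_i,r_j) P1 |AB>
                          = 2 [ g.(PA, QB)_x + g.(PAQ, B)_c
                              + g.(QBP, A)_c' + g.(PB, AQ)_c'' ]

with one Coulomb-tensor contraction per pattern (exchanged-exchanged,
exchanged-spectator, spectator-exchanged, spectator-spectator); see the
functions below for the exact index pairings.  These formulas were
validated term by term against explicit four-electron tensor algebra
(tests/test_exchange_oracle.py).

All energies through second order, for ground or excited states, reduce to
these primitives with the appropriate (transition) amplitudes.
"""

from __future__ import annotations

import numpy as np


def _exx(g, M1, M2):
    """sum_pqrs g[p,q,r,s] M1[p,s] M2[r,q]  (exchanged-exchanged pattern)."""
    return np.einsum("pqrs,ps,rq->", g, M1, M2, optimize=True)


def _dir(g, M1, M2):
    """sum_pqrs g[p,q,r,s] M1[p,r] M2[q,s]."""
    return np.einsum("pqrs,pr,qs->", g, M1, M2, optimize=True)


def _dir2(g, M1, M2):
    """sum_pqrs g[p,q,r,s] M1[p,q] M2[r,s]  (Coulomb-type pairing)."""
    return np.einsum("pqrs,pq,rs->", g, M1, M2, optimize=True)


class GeminalPairContractions:
    """S^2 matrix elements for two-electron monomers in one frame.

    Parameters are frame-space matrices: bra/ket geminals per monomer,
    nuclear potentials wA (of A's nuclei), wB, the frame Coulomb tensor g,
    and the nuclear-nuclear interaction scalar.
    """

    def __init__(self, g_X: np.ndarray, wA_X: np.ndarray, wB_X: np.ndarray,
                 vnn: float):
        self.g = g_X
        self.wA = wA_X
        self.wB = wB_X
        self.vnn = vnn

    def p1(self, P, A, Q, B) -> float:
        return 2.0 * float(np.trace(P @ A @ Q @ B))

    def v_p1(self, P, A, Q, B) -> float:
        """<PQ| V P1 |AB> with V the full intermolecular operator."""
        g = self.g
        PA = P @ A
        QB = Q @ B
        t = self.vnn * np.trace(PA @ QB)
        # one-body: B's nuclei act on A's electrons (coords 1, 2) ...
        t += np.trace(PA @ QB @ self.wB) + np.trace(P @ self.wB @ A @ QB)
        # ... A's nuclei act on B's electrons (coords 3, 4)
        t += np.trace(PA @ self.wA @ QB) + np.trace(PA @ Q @ self.wA @ B)
        # two-electron patterns
        t += _exx(g, PA, QB)                       # both coords exchanged
        t += _dir(g, PA @ Q, B)                    # exchanged(A) - spectator(B)
        t += np.einsum("yvzu,zy,uv->", g, QB @ P, A, optimize=True)
        t += np.einsum("yvwn,yn,vw->", g, P @ B, A @ Q, optimize=True)
        return 2.0 * float(t)

    def v_pol(self, P, A, Q, B) -> float:
        """<PQ| V |AB> without exchange (polarization matrix element)."""
        gamA = 2.0 * P @ A          # transition density <bra|E|ket> in frame
        gamB = 2.0 * Q @ B
        ovA = float(np.einsum("pq,pq->", P, A))   # <bra_A|ket_A>
        ovB = float(np.einsum("pq,pq->", Q, B))
        t = self.vnn * ovA * ovB
        t += np.trace(gamA @ self.wB) * ovB
        t += np.trace(gamB @ self.wA) * ovA
        t += _dir2(self.g, gamA, gamB)
        return float(t)


def electrostatic_energy_frame(gamA_X, gamB_X, wA_X, wB_X, g_X, vnn) -> float:
    """First-order electrostatics from frame-space spin-summed densities."""
    n = gamA_X.shape[0]
    J = (g_X.reshape(n * n, n * n) @ gamB_X.ravel()).reshape(n, n)
    return float(vnn + np.trace(gamA_X @ wB_X) + np.trace(gamB_X @ wA_X)
                 + np.sum(gamA_X * J))
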