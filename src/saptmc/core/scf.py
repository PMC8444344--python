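"""Closed-shell restricted Hartree-Fock with DIIS."""

from __future__ import annotations

import numpy as np


class SCFConvergenceError(RuntimeError):
    pass


def orthogonalizer(S: np.ndarray, lindep: float = 1e-9) -> np.ndarray:
    """Canonical orthogonalization; drops near-null-space combinations."""
    w, U = np.linalg.eigh(S)
    keep = w > lindep
    return U[:, keep] / np.sqrt(w[keep])


def rhf(hcore, eri, S, n_electrons, enuc=0.0, max_cycles=200, conv=1e-10,
        diis_size=8, level_shift=0.0, guess_dm=None):
    """Restricted HF.  Returns (energy, mo_coeffs, mo_energies, density).

    ``eri`` in chemists' notation (pq|rs); density is the spin-summed
    AO density matrix (idempotent*2 at convergence).
    """
    if n_electrons % 2:
        raise ValueError("RHF requires an even number of electrons")
    nocc = n_electrons // 2
    X = orthogonalizer(S)
    if guess_dm is None:
        f = X.T @ hcore @ X
        w, c = np.linalg.eigh(f)
        C = X @ c
        dm = 2.0 * C[:, :nocc] @ C[:, :nocc].T
    else:
        dm = guess_dm
    errs, focks = [], []
    e_old = 0.0
    for cycle in range(max_cycles):
        J = np.einsum("pqrs,rs->pq", eri, dm, optimize=True)
        K = np.einsum("prqs,rs->pq", eri, dm, optimize=True)
        F = hcore + J - 0.5 * K
        e = 0.5 * np.sum(dm * (hcore + F)) + enuc
        err = F @ dm @ S - S @ dm @ F
        err = X.T @ err @ X
        errs.append(err.ravel())
        focks.append(F)
        if len(errs) > diis_size:
            errs.pop(0)
            focks.pop(0)
        if cycle > 0 and np.linalg.norm(err) < 1e-7 and abs(e - e_old) < conv:
            break
        e_old = e
        # DIIS extrapolation
        if len(errs) > 1:
            n = len(errs)
            Bm = -np.ones((n + 1, n + 1))
            Bm[n, n] = 0.0
            for i in range(n):
                for j in range(n):
                    Bm[i, j] = errs[i] @ errs[j]
            rhs = np.zeros(n + 1)
            rhs[n] = -1.0
            try:
                cdi = np.linalg.solve(Bm, rhs)[:n]
                F = sum(ci * fi for ci, fi in zip(cdi, focks))
            except np.linalg.LinAlgError:
                pass
        f = X.T @ F @ X
        if level_shift:
            pass
        w, c = np.linalg.eigh(f)
        C = X @ c
        dm = 2.0 * C[:, :nocc] @ C[:, :nocc].T
    else:
        raise SCFConvergenceError("RHF did not converge")
    return e, C, w, dm
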