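"""Abelian point-group handling via coordinate sign flips.

For dimers oriented with symmetry planes on the coordinate planes (the
built-in T-shape generator does this), every C2v operation is a sign flip
of one or two axes, so its AO representation is a signed permutation.
Simultaneous diagonalization of the flip operators yields an orthonormal
symmetry-adapted basis with Z2 x Z2 irrep labels (encoded as two bits, so
products of irreps are XORs of labels).  The labels drive block
diagonalization in the two-electron and four-electron CI solvers.
"""

from __future__ import annotations

import numpy as np

from .basis import BasisSet
from .geometry import Molecule
from .scf import orthogonalizer

# per-l, per-m sign pattern exponents: sign = sx^ax * sy^ay * sz^az
_M_POWERS = {
    0: [(0, 0, 0)],
    1: [(1, 0, 0), (0, 1, 0), (0, 0, 1)],             # x, y, z
    2: [(1, 1, 0), (0, 1, 1), (0, 0, 0), (1, 0, 1), (0, 0, 0)],  # xy,yz,z2,xz,x2-y2
}


def detect_flip_ops(mol: Molecule, tol: float = 1e-8) -> list[tuple[int, int, int]]:
    """Axis sign-flip operations mapping the center set onto itself.

    A valid operation must map centers to centers with identical element,
    ghost flag, and charge.  Returns flips as (sx, sy, sz) excluding identity.
    """
    keys = [(a.element, a.ghost) for a in mol.atoms]
    coords = mol.coords
    ops = []
    for flip in [(-1, 1, 1), (1, -1, 1), (1, 1, -1),
                 (-1, -1, 1), (-1, 1, -1), (1, -1, -1), (-1, -1, -1)]:
        mapped = coords * np.array(flip)
        ok = True
        for i, mc in enumerate(mapped):
            hits = [j for j in range(len(coords))
                    if keys[j] == keys[i] and np.linalg.norm(coords[j] - mc) < tol]
            if not hits:
                ok = False
                break
        if ok:
            ops.append(flip)
    return ops


def flip_matrix(basis: BasisSet, flip: tuple[int, int, int], tol=1e-8) -> np.ndarray:
    """Signed-permutation AO matrix of an axis flip (includes norm pattern)."""
    n = basis.n_functions
    P = np.zeros((n, n))
    offsets = basis.shell_offsets()
    shells = basis.shells
    centers = np.array([s.center for s in shells])
    fl = np.array(flip, float)
    for i, sh in enumerate(shells):
        target = sh.center * fl
        # find the image shell: same l, exponents, at the mapped center
        img = None
        for j, sh2 in enumerate(shells):
            if sh2.l == sh.l and len(sh2.exps) == len(sh.exps) \
                    and np.allclose(sh2.exps, sh.exps) \
                    and np.linalg.norm(sh2.center - target) < tol:
                img = j
                break
        if img is None:
            raise ValueError("flip does not map the basis onto itself")
        for m, (ax, ay, az) in enumerate(_M_POWERS[sh.l]):
            s = (flip[0] ** ax) * (flip[1] ** ay) * (flip[2] ** az)
            P[offsets[img] + m, offsets[i] + m] = s
    return P


def mo_irrep_labels(basis: BasisSet, S: np.ndarray, C: np.ndarray,
                    mo_energies: np.ndarray | None = None,
                    degeneracy_tol: float = 1e-7):
    """Irrep labels for molecular orbitals; purifies degenerate mixtures.

    Returns (C_pure, labels).  Orbitals within a degenerate energy group are
    rotated into simultaneous eigenvectors of the flip operators; isolated
    orbitals are labeled by the sign of their diagonal operator elements.
    """
    ops = detect_flip_ops(basis.molecule)
    gens = [f for f in ops if sum(1 for s in f if s < 0) == 1]
    if not gens:
        gens = ops[:1]
    gens = gens[:2]
    nmo = C.shape[1]
    if not gens:
        return C, np.zeros(nmo, np.int64)
    mats = [C.T @ S @ flip_matrix(basis, f) @ C for f in gens]
    Cp = C.copy()
    if mo_energies is not None:
        # rotate within degenerate groups to purify
        groups = []
        start = 0
        for i in range(1, nmo + 1):
            if i == nmo or mo_energies[i] - mo_energies[start] > degeneracy_tol:
                groups.append(np.arange(start, i))
                start = i
        comb = mats[0] + (3.0 * mats[1] if len(mats) > 1 else 0.0)
        for grp in groups:
            if len(grp) == 1:
                continue
            blk = 0.5 * (comb[np.ix_(grp, grp)] + comb[np.ix_(grp, grp)].T)
            _, u = np.linalg.eigh(blk)
            Cp[:, grp] = Cp[:, grp] @ u
        mats = [Cp.T @ S @ flip_matrix(basis, f) @ Cp for f in gens]
    labels = np.zeros(nmo, np.int64)
    labels |= (np.diag(mats[0]) < 0).astype(np.int64)
    if len(mats) > 1:
        labels |= ((np.diag(mats[1]) < 0).astype(np.int64)) << 1
    return Cp, labels


def symmetry_adapted_basis(basis: BasisSet, S: np.ndarray,
                           lindep: float = 1e-9):
    """Orthonormal symmetry-adapted basis and 2-bit irrep labels.

    Uses up to two generating flips (x -> -x and y -> -y type); returns
    (X, labels) where columns of X are orthonormal w.r.t. S and labels are
    integers in {0,1,2,3} with XOR composition.  Falls back to a plain
    canonical orthogonalizer with all-zero labels when no symmetry exists.
    """
    X = orthogonalizer(S, lindep)
    ops = detect_flip_ops(basis.molecule)
    # pick up to two independent single-axis generators
    gens = [f for f in ops if sum(1 for s in f if s < 0) == 1]
    if not gens:
        gens = ops[:1]
    gens = gens[:2]
    if not gens:
        return X, np.zeros(X.shape[1], np.int64)
    mats = []
    for f in gens:
        P = flip_matrix(basis, f)
        # operator in the orthonormal frame
        mats.append(X.T @ S @ P @ X)
    # simultaneous eigenbasis of commuting involutions
    comb = mats[0] + (3.0 * mats[1] if len(mats) > 1 else 0.0)
    comb = 0.5 * (comb + comb.T)
    w, U = np.linalg.eigh(comb)
    Xs = X @ U
    labels = np.zeros(len(w), np.int64)
    s1 = np.einsum("ij,ji->i", U.T @ mats[0], U)
    labels |= (s1 < 0).astype(np.int64)
    if len(mats) > 1:
        s2 = np.einsum("ij,ji->i", U.T @ mats[1], U)
        labels |= ((s2 < 0).astype(np.int64)) << 1
    return Xs, labels
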