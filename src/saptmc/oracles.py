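"""Brute-force oracles: explicit tensor algebra for product wave functions.

Monomer wave functions are represented as explicit antisymmetric tensors
with one spin-orbital axis per electron, all over a common orthonormal
spatial basis.  Intermolecular operators (V), single-exchange operators
P_ij, and full cross-monomer antisymmetrizers act by tensor contraction
and axis permutation, with no density-matrix shortcuts — which makes this
module the independent reference implementation for every symmetry-adapted
perturbation theory matrix element in the package.  Cost grows as
(2M)^(N_A+N_B); intended for small bases and few-electron monomers.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def spinor_dim(norb: int) -> int:
    return 2 * norb


def geminal_tensor(C_common: np.ndarray) -> np.ndarray:
    """Two-electron singlet tensor from a (symmetric) spatial geminal matrix.

    Index convention: spin-orbital index x = 2*m + sigma (sigma 0=alpha).
    """
    m = C_common.shape[0]
    chi = np.zeros((2, 2))
    chi[0, 1] = 1.0 / math.sqrt(2.0)
    chi[1, 0] = -1.0 / math.sqrt(2.0)
    T = np.einsum("pq,st->psqt", C_common, chi).reshape(2 * m, 2 * m)
    return T


def determinant_tensor(orbs_spins: list[tuple[np.ndarray, int]]) -> np.ndarray:
    """Normalized Slater determinant as an explicit N-electron tensor.

    Each entry is (spatial orbital vector over the common basis, spin 0|1).
    """
    n = len(orbs_spins)
    m = len(orbs_spins[0][0])
    spinors = []
    for vec, s in orbs_spins:
        so = np.zeros(2 * m)
        so[2 * np.arange(m) + s] = vec
        spinors.append(so)
    T = np.zeros((2 * m,) * n)
    for perm in itertools.permutations(range(n)):
        sign = _perm_sign(perm)
        term = spinors[perm[0]]
        block = np.array(1.0)
        for k in perm:
            block = np.multiply.outer(block, spinors[k])
        T += sign * block
    return T / math.sqrt(math.factorial(n))


def _perm_sign(perm) -> int:
    s = 1
    perm = list(perm)
    for i in range(len(perm)):
        while perm[i] != i:
            j = perm[i]
            perm[i], perm[j] = perm[j], perm[i]
            s = -s
    return s


def ci_tensor(civec: np.ndarray, stra, strb, norb: int,
              orbital_coeffs: np.ndarray) -> np.ndarray:
    """N-electron tensor of a determinant-CI wave function.

    ``orbital_coeffs`` (M x norb) expresses the CI orbitals over the common
    orthonormal basis.  Alpha electrons come first in the determinant
    convention (matching core.ci.FCISolver).
    """
    na = bin(int(stra[0])).count("1")
    nb = bin(int(strb[0])).count("1")
    M = orbital_coeffs.shape[0]
    T = np.zeros((2 * M,) * (na + nb))
    v = civec.reshape(len(stra), len(strb))
    for ia, ma in enumerate(stra):
        occa = [p for p in range(norb) if int(ma) >> p & 1]
        for ib, mb in enumerate(strb):
            c = v[ia, ib]
            if abs(c) < 1e-14:
                continue
            occb = [p for p in range(norb) if int(mb) >> p & 1]
            os_ = [(orbital_coeffs[:, p], 0) for p in occa] + \
                  [(orbital_coeffs[:, p], 1) for p in occb]
            T += c * determinant_tensor(os_)
    return T


class ProductOracle:
    """Exact matrix elements over explicit monomer-product tensors.

    ``h_so``/``v_so`` are the spin-orbital one- and two-electron matrices of
    the *interaction* pieces (or any operator) over the common basis.
    """

    def __init__(self, nA: int, nB: int):
        self.nA = nA
        self.nB = nB
        self.n = nA + nB

    def product(self, TA: np.ndarray, TB: np.ndarray) -> np.ndarray:
        return np.multiply.outer(TA, TB)

    def overlap(self, T1: np.ndarray, T2: np.ndarray) -> float:
        return float(np.tensordot(T1, T2, axes=self.n))

    def apply_one_body(self, T: np.ndarray, w_so: np.ndarray,
                       electrons=None) -> np.ndarray:
        out = np.zeros_like(T)
        if electrons is None:
            electrons = range(self.n)
        for i in electrons:
            out += np.moveaxis(np.tensordot(w_so, T, axes=([1], [i])), 0, i)
        return out

    def apply_two_body(self, T: np.ndarray, v_so: np.ndarray,
                       pairs) -> np.ndarray:
        """Apply sum of v(i,j) over the given electron pairs.

        v_so[x,y,x',y'] = <x y| v |x' y'> (physicists' ordering over
        spin-orbitals).
        """
        out = np.zeros_like(T)
        for i, j in pairs:
            t = np.tensordot(v_so, T, axes=([2, 3], [i, j]))
            out += np.moveaxis(t, [0, 1], [i, j])
        return out

    def apply_p1(self, T: np.ndarray) -> np.ndarray:
        """Single-exchange operator: sum of transpositions across monomers."""
        out = np.zeros_like(T)
        for i in range(self.nA):
            for j in range(self.nA, self.n):
                out += np.swapaxes(T, i, j)
        return out

    def apply_antisymmetrizer(self, T: np.ndarray) -> np.ndarray:
        """Full intermonomer antisymmetrizer (coset sum, unnormalized):

        A = sum over ways of exchanging k electrons between A and B of
        (-1)^k (product of disjoint transpositions), i.e. the distinct-coset
        representatives; sufficient because monomer tensors are already
        antisymmetric internally.
        """
        out = np.zeros_like(T)
        aidx = range(self.nA)
        bidx = range(self.nA, self.n)
        for k in range(min(self.nA, self.nB) + 1):
            for asub in itertools.combinations(aidx, k):
                for bsub in itertools.permutations(bidx, k):
                    perm = list(range(self.n))
                    for x, y in zip(asub, bsub):
                        perm[x], perm[y] = perm[y], perm[x]
                    out += (-1) ** k * np.transpose(T, perm)
        return out

    # ---- interaction operator over the product space ------------------
    def interaction_tensors(self, wA_so, wB_so, v_so, vnn):
        """Bundle of the intermolecular operator pieces.

        wA_so: potential of A's nuclei (acts on B's electrons);
        wB_so: potential of B's nuclei (acts on A's electrons);
        v_so: electron-electron repulsion (physicists' ordering);
        vnn: nuclear-nuclear scalar.
        """
        return {"wA": wA_so, "wB": wB_so, "v": v_so, "vnn": vnn}

    def apply_V(self, T: np.ndarray, ops) -> np.ndarray:
        out = ops["vnn"] * T
        out += self.apply_one_body(T, ops["wB"], range(self.nA))
        out += self.apply_one_body(T, ops["wA"], range(self.nA, self.n))
        pairs = [(i, j) for i in range(self.nA) for j in range(self.nA, self.n)]
        out += self.apply_two_body(T, ops["v"], pairs)
        return out


def spin_orbital_one_body(w: np.ndarray) -> np.ndarray:
    m = w.shape[0]
    out = np.zeros((2 * m, 2 * m))
    out[0::2, 0::2] = w
    out[1::2, 1::2] = w
    return out


def spin_orbital_two_body(g_chem: np.ndarray) -> np.ndarray:
    """Spin-orbital <xy|v|x'y'> from spatial chemists' (pq|rs)."""
    m = g_chem.shape[0]
    v_phys = g_chem.transpose(0, 2, 1, 3)  # <pr|v|qs>
    out = np.zeros((2 * m,) * 4)
    for s1 in (0, 1):
        for s2 in (0, 1):
            out[s1::2, s2::2, s1::2, s2::2] = v_phys
    return out


def read_fcidump(path):
    """Minimal FCIDUMP reader: returns (h, g_chem, e_core, norb, nelec)."""
    import re
    with open(path) as f:
        text = f.read()
    header = re.search(r"&FCI(.*?)(/|&END)", text, re.S).group(1)
    norb = int(re.search(r"NORB\s*=\s*(\d+)", header).group(1))
    nelec = int(re.search(r"NELEC\s*=\s*(\d+)", header).group(1))
    body = text[text.index(re.search(r"(/|&END)", text).group(0)):]
    body = body.split("\n")[1:]
    h = np.zeros((norb, norb))
    g = np.zeros((norb, norb, norb, norb))
    ecore = 0.0
    for line in body:
        parts = line.split()
        if len(parts) != 5:
            continue
        val = float(parts[0])
        i, j, k, l = (int(x) for x in parts[1:])
        if i == j == k == l == 0:
            ecore = val
        elif k == l == 0:
            h[i - 1, j - 1] = h[j - 1, i - 1] = val
        else:
            for a, b in ((i - 1, j - 1), (j - 1, i - 1)):
                for c, d in ((k - 1, l - 1), (l - 1, k - 1)):
                    g[a, b, c, d] = g[c, d, a, b] = val
    return h, g, ecore, norb, nelec
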