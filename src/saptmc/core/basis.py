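"""Contracted Gaussian basis sets (spherical harmonics).

Basis parameters live in ``basis_library.json`` (Dunning correlation-
consistent and Pople sets for H and He).  Shells are flattened into plain
arrays for the compiled integral kernels.  All functions are real solid
harmonics; each contracted function is normalized numerically through the
overlap diagonal, which makes the final integrals independent of the
normalization conventions of the raw tables.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources

import numpy as np

from .geometry import Molecule

# cartesian component ordering per angular momentum: lists of (lx, ly, lz)
CART_COMPONENTS = {
    0: [(0, 0, 0)],
    1: [(1, 0, 0), (0, 1, 0), (0, 0, 1)],
    2: [(2, 0, 0), (1, 1, 0), (1, 0, 1), (0, 2, 0), (0, 1, 1), (0, 0, 2)],
}

# real solid harmonic combinations of cartesians (unnormalized; each
# spherical function is renormalized afterwards so only within-combination
# ratios matter).  d ordering: xy, yz, 3z^2-r^2, xz, x^2-y^2.
SPH_COMBOS = {
    0: [[(0, 1.0)]],
    1: [[(0, 1.0)], [(1, 1.0)], [(2, 1.0)]],
    2: [
        [(1, 1.0)],                          # xy
        [(4, 1.0)],                          # yz
        [(5, 1.0), (0, -0.5), (3, -0.5)],    # z2 - (x2+y2)/2
        [(2, 1.0)],                          # xz
        [(0, 1.0), (3, -1.0)],               # x2 - y2
    ],
}

N_SPH = {0: 1, 1: 3, 2: 5}
N_CART = {0: 1, 1: 3, 2: 6}


_LIBRARY_CACHE: dict | None = None


def _load_library() -> dict:
    global _LIBRARY_CACHE
    if _LIBRARY_CACHE is None:
        text = resources.files("saptmc.core").joinpath("basis_library.json").read_text()
        _LIBRARY_CACHE = json.loads(text)
    return _LIBRARY_CACHE


def _primitive_norm(alpha: float, l: int) -> float:
    """Norm of a cartesian primitive x^l exp(-a r^2) (the (l,0,0) component)."""
    df = 1.0
    for k in range(2 * l - 1, 0, -2):
        df *= k
    return (2 * alpha / np.pi) ** 0.75 * (4 * alpha) ** (l / 2) / np.sqrt(df)


@dataclass
class Shell:
    l: int
    center: np.ndarray
    exps: np.ndarray
    coefs: np.ndarray  # contraction coefficients including primitive norms


class BasisSet:
    """Spherical-harmonic Gaussian basis over the centers of a Molecule."""

    def __init__(self, molecule: Molecule, name: str):
        self.name = name.lower()
        lib = _load_library()
        if self.name not in lib:
            raise KeyError(f"basis '{name}' not in library "
                           f"(available: {sorted(lib)})")
        table = lib[self.name]
        self.shells: list[Shell] = []
        for atom in molecule.atoms:
            if atom.element not in table:
                raise KeyError(f"no '{name}' parameters for {atom.element}")
            for blk in table[atom.element]:
                exps = np.asarray(blk["exps"], float)
                coefs = np.asarray(blk["coefs"], float).copy()
                l = int(blk["l"])
                for i, a in enumerate(exps):
                    coefs[i] *= _primitive_norm(a, l)
                self.shells.append(Shell(l, atom.coord.copy(), exps, coefs))
        self.molecule = molecule
        self._offsets = np.cumsum([0] + [N_SPH[s.l] for s in self.shells])
        self.n_functions = int(self._offsets[-1])

    # ---- flattened arrays for the compiled kernels -------------------
    def flat_arrays(self):
        ls = np.array([s.l for s in self.shells], np.int64)
        centers = np.array([s.center for s in self.shells])
        prim_count = np.array([len(s.exps) for s in self.shells], np.int64)
        prim_start = np.concatenate([[0], np.cumsum(prim_count)[:-1]])
        exps = np.concatenate([s.exps for s in self.shells])
        coefs = np.concatenate([s.coefs for s in self.shells])
        return ls, centers, prim_start.astype(np.int64), prim_count, exps, coefs

    def shell_offsets(self) -> np.ndarray:
        return self._offsets
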