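"""Interaction integrals in the mixed natural-orbital bases of two monomers.

Internally everything is referred to one orthonormal frame X spanning the
dimer-centered basis (the monomer workspaces provide it).  Monomer NO sets
are orthogonal matrices U_A, U_B in that frame, so the cross-monomer overlap
is S = U_A^T U_B and any mixed-basis integral block is a four-index
transform of the frame tensor; blocks are materialized on demand and cached.
"""

from __future__ import annotations

import numpy as np

from .core.geometry import interaction_nuclear_repulsion
from .core.mo import transform_eri
from .monomer import DimerJob, MonomerState, MonomerWorkspace


class NOIntegrals:
    """Overlaps, one-electron potentials, Coulomb blocks and embedding
    potentials for a monomer pair at one geometry."""

    def __init__(self, workspace: MonomerWorkspace, state_a: MonomerState,
                 state_b: MonomerState):
        ws = workspace
        self.ws = ws
        SX = ws.ints.S
        self.U_a = ws.X.T @ SX @ state_a.no_coeffs
        self.U_b = ws.X.T @ SX @ state_b.no_coeffs
        self.S = self.U_a.T @ self.U_b            # cross-monomer NO overlap
        self.vA_X = ws._v["A"]                    # potential of A's nuclei
        self.vB_X = ws._v["B"]
        self.V_AB_nuc = interaction_nuclear_repulsion(
            ws.job.geometry_a, ws.job.geometry_b)
        self._blocks: dict[str, np.ndarray] = {}
        # frame-space spin-summed densities
        self.gamma_a_X = self.U_a @ state_a.gamma1 @ self.U_a.T
        self.gamma_b_X = self.U_b @ state_b.gamma1 @ self.U_b.T

    # ---- two-electron blocks ------------------------------------------
    def eri(self, tags: str) -> np.ndarray:
        """Mixed-NO Coulomb block, e.g. 'AABB' = (a a | b b) in chemists'
        notation.  Cached; call drop_eri_cache() to release memory."""
        tags = tags.upper()
        if tags not in self._blocks:
            cs = [self.U_a if t == "A" else self.U_b for t in tags]
            self._blocks[tags] = transform_eri(self.ws.g_X, *cs)
        return self._blocks[tags]

    def drop_eri_cache(self):
        self._blocks.clear()

    def coulomb_X(self, dm_X: np.ndarray) -> np.ndarray:
        """Frame-space Coulomb matrix J[D]_pq = sum_rs (pq|rs) D_rs."""
        n = dm_X.shape[0]
        return (self.ws.g_X.reshape(n * n, n * n) @ dm_X.ravel()).reshape(n, n)

    # ---- one-electron & embedding -------------------------------------
    def v_block(self, which: str, row: str, col: str) -> np.ndarray:
        """Potential of monomer `which`'s nuclei between NO sets row/col."""
        v = self.vA_X if which.upper() == "A" else self.vB_X
        ur = self.U_a if row.upper() == "A" else self.U_b
        uc = self.U_a if col.upper() == "A" else self.U_b
        return ur.T @ v @ uc

    def embedding_potential(self, source: str) -> np.ndarray:
        """Omega matrix of monomer `source` in the partner's NO basis.

        Omega_B (source='B') collects the electrostatic potential of B's
        nuclei and its unperturbed electron density, expressed over A's NOs.
        """
        if source.upper() == "B":
            om_X = self.vB_X + self.coulomb_X(self.gamma_b_X)
            u = self.U_a
        else:
            om_X = self.vA_X + self.coulomb_X(self.gamma_a_X)
            u = self.U_b
        return u.T @ om_X @ u

    def embedding_potential_X(self, source: str) -> np.ndarray:
        if source.upper() == "B":
            return self.vB_X + self.coulomb_X(self.gamma_b_X)
        return self.vA_X + self.coulomb_X(self.gamma_a_X)


def build_integrals(state_a: MonomerState, state_b: MonomerState,
                    workspace: MonomerWorkspace) -> NOIntegrals:
    return NOIntegrals(workspace, state_a, state_b)
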