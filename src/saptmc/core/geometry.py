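"""Molecular geometries with ghost-atom support.

A :class:`Molecule` is a list of centers.  Each center carries a nuclear
charge (zero for ghost atoms, which contribute basis functions only — the
mechanism behind dimer-centered basis sets and counterpoise corrections)
and an element label used to look up its basis functions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

BOHR_PER_ANGSTROM = 1.0 / 0.529177210903

_Z = {"H": 1, "He": 2, "Li": 3, "Be": 4, "B": 5, "C": 6, "N": 7, "O": 8,
     "F": 9, "Ne": 10, "Ar": 18}


@dataclass
class Atom:
    element: str          # element symbol used for basis lookup
    coord: np.ndarray     # position in bohr, shape (3,)
    ghost: bool = False   # ghost centers carry basis functions, no charge

    @property
    def charge(self) -> float:
        return 0.0 if self.ghost else float(_Z[self.element])


@dataclass
class Molecule:
    atoms: list[Atom] = field(default_factory=list)

    @classmethod
    def from_list(cls, spec, unit: str = "bohr") -> "Molecule":
        """Build from ``[(element, x, y, z), ...]``; unit is 'bohr' or 'angstrom'.

        An element prefixed with ``@`` (e.g. ``"@H"``) marks a ghost center.
        """
        scale = 1.0 if unit.lower().startswith("b") else BOHR_PER_ANGSTROM
        atoms = []
        for el, x, y, z in spec:
            ghost = el.startswith("@")
            el = el.lstrip("@")
            atoms.append(Atom(el, np.array([x, y, z], float) * scale, ghost))
        return cls(atoms)

    def translated(self, shift) -> "Molecule":
        shift = np.asarray(shift, float)
        return Molecule([Atom(a.element, a.coord + shift, a.ghost) for a in self.atoms])

    def ghosted(self) -> "Molecule":
        """Copy with every center turned into a ghost."""
        return Molecule([Atom(a.element, a.coord.copy(), True) for a in self.atoms])

    def __add__(self, other: "Molecule") -> "Molecule":
        return Molecule([Atom(a.element, a.coord.copy(), a.ghost)
                         for a in self.atoms + other.atoms])

    @property
    def charges(self) -> np.ndarray:
        return np.array([a.charge for a in self.atoms])

    @property
    def coords(self) -> np.ndarray:
        return np.array([a.coord for a in self.atoms])

    def nuclear_repulsion(self) -> float:
        e = 0.0
        for i, a in enumerate(self.atoms):
            for b in self.atoms[:i]:
                if a.charge and b.charge:
                    e += a.charge * b.charge / np.linalg.norm(a.coord - b.coord)
        return e

    def n_electrons_neutral(self) -> int:
        return int(round(sum(a.charge for a in self.atoms)))


def interaction_nuclear_repulsion(mol_a: Molecule, mol_b: Molecule) -> float:
    """Nuclear repulsion between the (non-ghost) nuclei of two fragments."""
    e = 0.0
    for a in mol_a.atoms:
        for b in mol_b.atoms:
            if a.charge and b.charge:
                e += a.charge * b.charge / np.linalg.norm(a.coord - b.coord)
    return e


def h2_dimer_tshape(r_stretch: float, r_fixed: float = 1.44,
                    separation: float = 6.21,
                    stretched_on_axis: bool = False,
                    convention: str = "midpoint") -> tuple[Molecule, Molecule]:
    """T-shaped H2···H2 geometry (coordinates in bohr).

    Monomer A is the stretched molecule, monomer B is held at ``r_fixed``.
    ``separation`` is interpreted according to ``convention``:

    * ``"midpoint"`` — distance between the two bond midpoints (equal to the
      center-of-mass distance for homonuclear diatomics);
    * ``"nearest-atoms"`` — distance between the closest pair of atoms, one
      from each monomer, held fixed as the bond stretches.  This is the
      protocol of the bond-dissociation benchmark study: the interacting
      atoms stay at constant range while the covalent bond is broken.

    By default the stretched monomer forms the top bar of the T
    (perpendicular to the intermonomer axis, bisected by it) and the fixed
    monomer lies along the axis; ``stretched_on_axis=True`` swaps the roles.

    The dimer is oriented with the intermonomer axis along z and the
    perpendicular bond along x, so all C2v symmetry operations are
    coordinate sign flips.
    """
    half_a, half_b = 0.5 * r_stretch, 0.5 * r_fixed
    if convention == "midpoint":
        mid = separation
    elif convention in ("nearest-atoms", "nearest_atoms"):
        half_perp = half_b if stretched_on_axis else half_a
        inner = separation ** 2 - half_perp ** 2
        if inner <= 0:
            raise ValueError("separation shorter than half the perpendicular "
                             "bond: no such T-shape")
        mid = half_b + np.sqrt(inner) if not stretched_on_axis \
            else half_a + np.sqrt(inner)
    else:
        raise ValueError(f"unknown separation convention '{convention}'")
    if stretched_on_axis:
        mol_a = Molecule.from_list([("H", 0, 0, -half_a), ("H", 0, 0, half_a)])
        mol_b = Molecule.from_list([("H", -half_b, 0, mid),
                                    ("H", half_b, 0, mid)])
    else:
        mol_a = Molecule.from_list([("H", -half_a, 0, 0), ("H", half_a, 0, 0)])
        mol_b = Molecule.from_list([("H", 0, 0, mid - half_b),
                                    ("H", 0, 0, mid + half_b)])
    return mol_a, mol_b
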