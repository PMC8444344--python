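"""Monomer wave-function backend.

Produces monomer states (natural orbitals, occupation numbers, spin-summed
2-RDM) in the dimer-centered basis: the partner's centers enter as ghost
atoms carrying basis functions only.  Supported treatments: RHF, CASSCF,
state-averaged CASSCF, GVB (two-electron monomers, where GVB-PP coincides
with CAS(2,2)) and FCI for two-electron monomers.  States computed
externally (e.g. GVB for larger monomers) can be loaded from HDF5.

Conventions
-----------
Occupation numbers are per spin, ``n_p in [0, 1]`` with ``sum_p n_p = N/2``.
The spin-summed 2-RDM is stored in chemists' pairing over the occupied
orbital block: ``D[p,q,r,s] = sum_{st} <a+_{p s} a+_{r t} a_{s t} a_{q s}>``
so that ``E = sum h*gamma + 1/2 sum (pq|rs) D[p,q,r,s]``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np

from .core.basis import BasisSet
from .core.geometry import Molecule
from .core.integrals import AOIntegrals
from .core.mcscf import casscf_general, casscf_two_electron
from .core.mo import transform_eri, transform_matrix
from .core.scf import rhf
from .core.symmetry import symmetry_adapted_basis
from .core.ci import FCISolver, TwoElectronStates


@dataclass
class ThresholdSet:
    pair_degeneracy_gvb: float = 1e-2
    pair_degeneracy_cas: float = 1e-6
    s1_occ_cutoff_gvb: float = 0.992
    metric_zero_tol: float = 1e-10
    eig_positive_tol: float = 1e-8

    def __post_init__(self):
        for name, v in self.__dict__.items():
            if v <= 0:
                raise ValueError(f"threshold {name} must be positive")


_METHOD_RE = re.compile(
    r"^(?:(sa)-)?(hf|fci|gvb|cas)(?:\((\d+),(\d+)(?:,(\d+))?\))?$", re.I)


@dataclass
class MethodSpec:
    kind: str                 # 'hf' | 'cas' | 'gvb' | 'fci'
    n_elec_active: int = 0
    n_orb_active: int = 0
    n_sa_states: int = 1      # equal-weight state averaging

    @classmethod
    def parse(cls, text: str) -> "MethodSpec":
        m = _METHOD_RE.match(text.strip().lower())
        if not m:
            raise ValueError(f"cannot parse method '{text}'")
        sa, kind, ne, no, k = m.groups()
        spec = cls(kind=kind)
        if kind == "cas":
            if ne is None:
                raise ValueError("CAS requires (n_elec,n_orb)")
            spec.n_elec_active = int(ne)
            spec.n_orb_active = int(no)
            if sa:
                spec.n_sa_states = int(k) if k else 1
        elif kind == "gvb":
            spec.n_elec_active, spec.n_orb_active = 2, 2
        return spec


@dataclass
class DimerJob:
    geometry_a: Molecule
    geometry_b: Molecule
    basis: str
    method_a: str = "hf"
    method_b: str = "hf"
    state_a: int = 0
    state_b: int = 0
    thresholds: ThresholdSet = field(default_factory=ThresholdSet)
    negative_transitions: bool = True

    def __post_init__(self):
        ca = {tuple(np.round(a.coord, 10)) for a in self.geometry_a.atoms}
        cb = {tuple(np.round(a.coord, 10)) for a in self.geometry_b.atoms}
        if ca & cb:
            raise ValueError("monomer atom lists must be disjoint")
        for ms, st in [(self.method_a, self.state_a), (self.method_b, self.state_b)]:
            spec = MethodSpec.parse(ms)
            if st >= max(spec.n_sa_states, 1) and spec.kind in ("cas",):
                raise ValueError(
                    f"state index {st} outside the {spec.n_sa_states}-state ensemble")

    def dimer_molecule(self) -> Molecule:
        return self.geometry_a + self.geometry_b

    def monomer_molecule(self, which: str) -> Molecule:
        """Monomer with the partner as ghost centers (dimer-centered basis)."""
        if which.upper() == "A":
            return self.geometry_a + self.geometry_b.ghosted()
        return self.geometry_a.ghosted() + self.geometry_b


@dataclass
class MonomerState:
    no_coeffs: np.ndarray        # AO x n_orb natural-orbital coefficients
    occ: np.ndarray              # per-spin occupations, descending
    rdm2: np.ndarray | None      # spin-summed 2-RDM over the occupied block
    n_electrons: int
    state_index: int
    energy: float
    s1: np.ndarray               # inactive orbital indices (NO ordering)
    s2: np.ndarray               # active
    s3: np.ndarray               # virtual
    method: str = ""
    geminal: np.ndarray | None = None   # two-electron amplitude matrix (NO basis)
    label: str = ""
    n_occupied: int = 0          # size of the occupied (s1 u s2) block

    def __post_init__(self):
        ns = self.n_electrons / 2.0
        if abs(self.occ.sum() - ns) > 1e-8:
            raise ValueError(
                f"occupations sum to {self.occ.sum()}, expected N/2 = {ns}")
        if np.any(np.diff(self.occ) > 1e-10):
            raise ValueError("occupations must be sorted descending")
        if self.n_occupied == 0:
            self.n_occupied = self.rdm2.shape[0] if self.rdm2 is not None \
                else len(self.s1) + len(self.s2)
        if self.rdm2 is not None:
            self._check_rdm2_trace()

    def _check_rdm2_trace(self, tol: float = 1e-7):
        # partial trace: sum_r D[p,q,r,r] = (N - 1) * gamma_pq  (spin-summed)
        n = self.rdm2.shape[0]
        tr = np.einsum("pqrr->pq", self.rdm2)
        gam = 2.0 * self.occ[:n]
        ref = (self.n_electrons - 1) * np.diag(gam)
        if np.abs(tr - ref).max() > tol * max(1.0, self.n_electrons):
            raise ValueError("2-RDM partial trace inconsistent with occupations")

    def get_rdm2(self) -> np.ndarray:
        """Occupied-block spin-summed 2-RDM (built from the geminal if lazy)."""
        if self.rdm2 is None:
            if self.geminal is None:
                raise ValueError("state has neither a stored 2-RDM nor a geminal")
            n = self.n_occupied
            Cn = self.geminal[:n, :n]
            self.rdm2 = 2.0 * np.einsum("pr,qs->pqrs", Cn, Cn)
            self._check_rdm2_trace()
        return self.rdm2

    @property
    def gamma1(self) -> np.ndarray:
        """Spin-summed 1-RDM in the NO basis (diagonal)."""
        return np.diag(2.0 * self.occ)

    def save(self, path):
        import h5py
        import json
        with h5py.File(path, "w") as f:
            f["coeffs"] = self.no_coeffs
            f["occ"] = self.occ
            f["rdm2"] = self.rdm2
            if self.geminal is not None:
                f["geminal"] = self.geminal
            for name in ("s1", "s2", "s3"):
                f[name] = getattr(self, name)
            f.attrs["meta"] = json.dumps({
                "N": self.n_electrons, "state": self.state_index,
                "energy": self.energy, "method": self.method,
                "label": self.label})

    @classmethod
    def load(cls, path) -> "MonomerState":
        import h5py
        import json
        with h5py.File(path, "r") as f:
            meta = json.loads(f.attrs["meta"])
            return cls(
                no_coeffs=f["coeffs"][...], occ=f["occ"][...],
                rdm2=f["rdm2"][...],
                n_electrons=int(meta["N"]), state_index=int(meta["state"]),
                energy=float(meta["energy"]),
                s1=f["s1"][...], s2=f["s2"][...], s3=f["s3"][...],
                method=meta.get("method", ""),
                geminal=f["geminal"][...] if "geminal" in f else None,
                label=meta.get("label", ""))


def load_monomer(path) -> MonomerState:
    return MonomerState.load(path)


class MonomerWorkspace:
    """Integrals shared by all monomer/oracle work at one dimer geometry.

    Holds the dimer-centered AO integrals, a symmetry-adapted orthonormal
    basis X with abelian irrep labels, and the two-electron integrals
    transformed to that basis (the expensive step, done once).
    """

    def __init__(self, job: DimerJob, with_eri: bool = True):
        self.job = job
        mol = job.dimer_molecule()
        self.basis = BasisSet(mol, job.basis)
        self.ints = AOIntegrals(self.basis, with_eri=with_eri)
        self.X, self.labels = symmetry_adapted_basis(self.basis, self.ints.S)
        self._g_X = None
        # one-electron pieces per monomer (own nuclei only)
        self.kin_X = transform_matrix(self.ints.T, self.X)
        self._v = {}
        for which, mono in (("A", job.geometry_a), ("B", job.geometry_b)):
            charges = mono.charges
            live = charges != 0
            V = self.ints.point_charge_potential(charges[live], mono.coords[live])
            self._v[which] = transform_matrix(V, self.X)

    @property
    def g_X(self) -> np.ndarray:
        if self._g_X is None:
            self._g_X = transform_eri(self.ints.eri, self.X)
        return self._g_X

    def drop_ao_eri(self):
        """Free the AO two-electron tensor once transforms are done."""
        if self._g_X is None:
            _ = self.g_X
        self.ints.eri = None

    def h_X(self, which: str) -> np.ndarray:
        return self.kin_X + self._v[which.upper()]

    def enuc(self, which: str) -> float:
        mono = self.job.geometry_a if which.upper() == "A" else self.job.geometry_b
        return mono.nuclear_repulsion()

    def n_electrons(self, which: str) -> int:
        mono = self.job.geometry_a if which.upper() == "A" else self.job.geometry_b
        return mono.n_electrons_neutral()


def _partition_from_method(spec: MethodSpec, occ: np.ndarray, norb: int,
                           thr: ThresholdSet):
    """s1/s2/s3 orbital index sets in the NO (descending-occupation) order."""
    nelec = int(round(2 * occ.sum()))
    if spec.kind == "hf":
        nocc = nelec // 2
        return (np.arange(nocc), np.arange(0), np.arange(nocc, norb))
    if spec.kind == "fci":
        # fully correlated: every orbital is active
        return (np.arange(0), np.arange(norb), np.arange(0))
    if spec.kind == "gvb":
        s1 = np.where(occ > thr.s1_occ_cutoff_gvb)[0]
        strong = np.where((occ <= thr.s1_occ_cutoff_gvb) & (occ >= 0.5))[0]
        # geminal partners: under descending-occupation ordering the weakly
        # occupied partners immediately follow the strongly occupied set
        npair = len(strong)
        weak = np.arange(len(s1) + len(strong), len(s1) + len(strong) + npair)
        s2 = np.sort(np.concatenate([strong, weak]))
        rest = np.setdiff1d(np.arange(norb), np.concatenate([s1, s2]))
        return (s1, s2, rest)
    # CAS: inactive doubly occupied, active, virtual (descending occupation)
    ncore = max((nelec - spec.n_elec_active) // 2, 0)
    s1 = np.arange(ncore)
    s2 = np.arange(ncore, ncore + spec.n_orb_active)
    s3 = np.arange(ncore + spec.n_orb_active, norb)
    return (s1, s2, s3)


def partition_orbitals(state: MonomerState, method: str,
                       thresholds: ThresholdSet | None = None):
    """Recompute the (s1, s2, s3) partition for a state."""
    thr = thresholds or ThresholdSet()
    spec = MethodSpec.parse(method)
    norb = state.no_coeffs.shape[1]
    return _partition_from_method(spec, state.occ, norb, thr)


def _hf_rdm2(nocc: int) -> np.ndarray:
    gam = 2.0 * np.eye(nocc)
    return np.einsum("pq,rs->pqrs", gam, gam) \
        - 0.5 * np.einsum("ps,rq->pqrs", gam, gam)


def _geminal_state(C_gem: np.ndarray, X: np.ndarray, energy: float,
                   n_elec: int, state_index: int, spec: MethodSpec,
                   thr: ThresholdSet, method_label: str,
                   n_active: int | None = None) -> MonomerState:
    """Assemble a two-electron MonomerState from a geminal amplitude matrix.

    ``C_gem`` is expressed over the orthonormal basis X spans.  Natural
    orbitals follow from its spectral decomposition: C = sum_k c_k u_k u_k^T,
    n_k = c_k^2.
    """
    c, U = np.linalg.eigh(C_gem)
    order = np.argsort(-np.abs(c))
    c = c[order]
    U = U[:, order]
    # deterministic phases: largest-magnitude coefficient positive
    for k in range(U.shape[1]):
        j = np.argmax(np.abs(U[:, k]))
        if U[j, k] < 0:
            U[:, k] *= -1
    occ = c ** 2
    nos = X @ U
    ngem = np.diag(c)  # geminal is diagonal in its own NO basis
    nocc = n_active if n_active else int((occ > 1e-14).sum())
    nocc = max(nocc, 1)
    Cn = ngem[:nocc, :nocc]
    rdm2 = 2.0 * np.einsum("pr,qs->pqrs", Cn, Cn)
    s1, s2, s3 = _partition_from_method(spec, occ, len(occ), thr)
    return MonomerState(
        no_coeffs=nos, occ=occ, rdm2=rdm2, n_electrons=2,
        state_index=state_index, energy=energy, s1=s1, s2=s2, s3=s3,
        method=method_label, geminal=np.diag(c))


def compute_monomer(job: DimerJob, which: str,
                    workspace: MonomerWorkspace | None = None) -> MonomerState:
    """Monomer state in the dimer-centered basis via the embedded engine."""
    return compute_monomer_ensemble(job, which, workspace)[0 if True else 0]


def compute_monomer_ensemble(job: DimerJob, which: str,
                             workspace: MonomerWorkspace | None = None,
                             n_states: int | None = None) -> list[MonomerState]:
    """States 0..I of a monomer (I = requested state index), ground first.

    Always returns the requested state as element [-1]; lower states are
    included because the negative-transition machinery needs them.
    """
    ws = workspace or MonomerWorkspace(job)
    which = which.upper()
    method = job.method_a if which == "A" else job.method_b
    target = job.state_a if which == "A" else job.state_b
    spec = MethodSpec.parse(method)
    nel = ws.n_electrons(which)
    h = ws.h_X(which)
    enuc = ws.enuc(which)
    thr = job.thresholds

    if spec.kind == "hf":
        if target != 0:
            raise ValueError("HF supports the ground state only")
        e, C, weps, dm = rhf(h, ws.g_X, np.eye(h.shape[0]), nel, enuc)
        nocc = nel // 2
        occ = np.zeros(h.shape[0])
        occ[:nocc] = 1.0
        s1, s2, s3 = _partition_from_method(spec, occ, h.shape[0], thr)
        gem = None
        if nel == 2:
            gem = np.zeros((h.shape[0], h.shape[0]))
            gem[0, 0] = 1.0
        st = MonomerState(no_coeffs=ws.X @ C, occ=occ, rdm2=_hf_rdm2(nocc),
                          n_electrons=nel, state_index=0, energy=e,
                          s1=s1, s2=s2, s3=s3, method=method, geminal=gem)
        return [st]

    if nel == 2:
        return _two_electron_states(ws, which, spec, target, method, h, enuc, thr,
                                    n_states)
    return _general_cas_states(ws, which, spec, target, method, h, enuc, thr)


def _two_electron_states(ws, which, spec, target, method, h, enuc, thr,
                         n_states=None):
    g = ws.g_X
    nst = n_states if n_states is not None else target + 1
    if spec.kind == "fci":
        tes = TwoElectronStates(h, g, irreps=ws.labels, enuc=enuc)
        out = []
        for k in range(nst):
            out.append(_geminal_state(tes.geminals[k], ws.X, tes.energies[k],
                                      2, k, spec, thr, method))
        return out
    # CAS / GVB: state-specific or state-averaged orbital optimization
    n_avg = max(spec.n_sa_states, target + 1)
    res = casscf_two_electron(h, g, spec.n_orb_active,
                              n_avg=n_avg, enuc=enuc, irreps=ws.labels)
    if not res.converged:
        raise RuntimeError(f"CASSCF for monomer {which} did not converge "
                           f"(|g|={res.grad_norm:.1e})")
    Uact = res.mo_coeffs[:, : spec.n_orb_active]
    out = []
    for k in range(nst):
        A = _active_geminal(res.ci_vectors[:, k], spec.n_orb_active)
        C_gem = Uact @ A @ Uact.T
        out.append(_geminal_state(C_gem, ws.X, res.state_energies[k], 2, k,
                                  spec, thr, method, n_active=spec.n_orb_active))
    return out


def _active_geminal(vec: np.ndarray, m: int) -> np.ndarray:
    from .core.mcscf import _unpack_pair
    return _unpack_pair(vec, m)


def _general_cas_states(ws, which, spec, target, method, h, enuc, thr):
    g = ws.g_X
    nel = ws.n_electrons(which)
    ncore = (nel - spec.n_elec_active) // 2
    e, C, weps, dm = rhf(h, g, np.eye(h.shape[0]), nel, enuc)
    n_avg = max(spec.n_sa_states, target + 1)
    res = casscf_general(h, g, ncore, spec.n_orb_active, spec.n_elec_active,
                         n_avg=n_avg, enuc=enuc, u0=C)
    if not res.converged:
        raise RuntimeError(f"CASSCF for monomer {which} did not converge")
    hm = res.mo_coeffs.T @ h @ res.mo_coeffs
    gm = transform_eri(g, res.mo_coeffs)
    from .core.mcscf import _core_quantities
    ecore, heff = _core_quantities(hm, gm, ncore)
    act = slice(ncore, ncore + spec.n_orb_active)
    solver = FCISolver(heff[act, act], gm[act, act, act, act],
                       spec.n_elec_active)
    out = []
    for k in range(target + 1):
        wk, Vk = solver.solve_singlets(k + 1)
        v = Vk[:, k]
        d1a = solver.trdm1(v, v)
        d2a = solver.trdm2(v, v)
        # natural orbitals: diagonalize active 1-RDM, keep core/virtual
        wno, Uact = np.linalg.eigh(d1a)
        order = np.argsort(-wno)
        wno, Uact = wno[order], Uact[:, order]
        for kk in range(Uact.shape[1]):
            j = np.argmax(np.abs(Uact[:, kk]))
            if Uact[j, kk] < 0:
                Uact[:, kk] *= -1
        U = np.eye(h.shape[0])
        U[act, act] = Uact
        mos = res.mo_coeffs @ U
        occ = np.zeros(h.shape[0])
        occ[:ncore] = 1.0
        occ[act] = 0.5 * wno
        # rotate active RDMs into the NO basis
        d1n = Uact.T @ d1a @ Uact
        d2n = np.einsum("pqrs,pa,qb,rc,sd->abcd", d2a, Uact, Uact, Uact, Uact,
                        optimize=True)
        nocc = ncore + spec.n_orb_active
        rdm2 = _compose_cas_rdm2(ncore, spec.n_orb_active, d1n, d2n)
        s1, s2, s3 = _partition_from_method(spec, occ, h.shape[0], thr)
        out.append(MonomerState(
            no_coeffs=ws.X @ mos, occ=occ, rdm2=rdm2, n_electrons=nel,
            state_index=k, energy=res.state_energies[k], s1=s1, s2=s2, s3=s3,
            method=method))
    return out


def _compose_cas_rdm2(ncore: int, nact: int, d1a: np.ndarray,
                      d2a: np.ndarray) -> np.ndarray:
    """Full occupied-block spin-summed 2-RDM from core + active parts.

    Uses the exact cumulant structure of a CAS wave function: the core is
    uncorrelated, so D = gamma*gamma - 1/2 gamma^ex + active cumulant.
    """
    nocc = ncore + nact
    gam = np.zeros((nocc, nocc))
    gam[:ncore, :ncore] = 2.0 * np.eye(ncore)
    gam[ncore:, ncore:] = d1a
    D = np.einsum("pq,rs->pqrs", gam, gam) - 0.5 * np.einsum("ps,rq->pqrs", gam, gam)
    a = slice(ncore, nocc)
    lam = d2a - (np.einsum("pq,rs->pqrs", d1a, d1a)
                 - 0.5 * np.einsum("ps,rq->pqrs", d1a, d1a))
    D[a, a, a, a] += lam
    return D
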