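"""Gaussian integrals over contracted spherical-harmonic shells.

McMurchie–Davidson scheme: cartesian Gaussian products are expanded in
Hermite Gaussians (E coefficients); Coulomb-type integrals contract the
Hermite expansions with Boys-function derivatives (R tensor).  Kernels are
numba-compiled; angular momentum through d is supported, which covers the
correlation-consistent sets shipped with the package.

Every contracted function is renormalized through the overlap diagonal, so
the raw solid-harmonic scaling conventions drop out.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

from .basis import BasisSet, CART_COMPONENTS, SPH_COMBOS

_MAXL = 2

# padded cart->sph transform table TR[l, m, c] and cartesian powers
_TR = np.zeros((_MAXL + 1, 5, 6))
_CARTPOW = np.zeros((_MAXL + 1, 6, 3), np.int64)
for _l, _combos in SPH_COMBOS.items():
    for _m, _terms in enumerate(_combos):
        for _c, _w in _terms:
            _TR[_l, _m, _c] = _w
for _l, _comps in CART_COMPONENTS.items():
    for _c, (_lx, _ly, _lz) in enumerate(_comps):
        _CARTPOW[_l, _c] = (_lx, _ly, _lz)
_NSPH = np.array([1, 3, 5], np.int64)
_NCART = np.array([1, 3, 6], np.int64)


@njit(cache=True)
def _boys(mmax, T, out):
    if T < 1e-13:
        for m in range(mmax + 1):
            out[m] = 1.0 / (2 * m + 1)
        return
    if T < 40.0:
        s = 0.0
        term = 1.0 / (2 * mmax + 1)
        k = 0
        while True:
            s += term
            k += 1
            term *= 2.0 * T / (2 * mmax + 2 * k + 1)
            if term < 1e-17 * s or k > 300:
                break
        eT = math.exp(-T)
        out[mmax] = s * eT
        for m in range(mmax, 0, -1):
            out[m - 1] = (2.0 * T * out[m] + eT) / (2 * m - 1)
    else:
        eT = math.exp(-T)
        out[0] = 0.5 * math.sqrt(math.pi / T)
        for m in range(mmax):
            out[m + 1] = ((2 * m + 1) * out[m] - eT) / (2.0 * T)


@njit(cache=True)
def _efill(l1, l2, A, B, a, b, E):
    """Hermite expansion coefficients for one dimension.

    E[i, j, t] for x^i on A times x^j on B; E[0,0,0] carries the Gaussian
    product prefactor exp(-mu*Xab^2).
    """
    p = a + b
    mu = a * b / p
    X = A - B
    PA = -b * X / p
    PB = a * X / p
    E[:, :, :] = 0.0
    E[0, 0, 0] = math.exp(-mu * X * X)
    oo2p = 0.5 / p
    for i in range(l1 + 1):
        for j in range(l2 + 1):
            if i == 0 and j == 0:
                continue
            for t in range(i + j + 1):
                v = 0.0
                if j == 0:
                    if t - 1 >= 0:
                        v += oo2p * E[i - 1, j, t - 1]
                    v += PA * E[i - 1, j, t]
                    if t + 1 <= i + j - 1:
                        v += (t + 1) * E[i - 1, j, t + 1]
                else:
                    if t - 1 >= 0:
                        v += oo2p * E[i, j - 1, t - 1]
                    v += PB * E[i, j - 1, t]
                    if t + 1 <= i + j - 1:
                        v += (t + 1) * E[i, j - 1, t + 1]
                E[i, j, t] = v
    return p


@njit(cache=True)
def _rfill(L, alpha, X, Y, Z, T, R):
    """Hermite Coulomb tensor R[t,u,v] at auxiliary order 0 (t+u+v <= L)."""
    F = np.zeros(L + 1)
    _boys(L, T, F)
    Rn = np.zeros((L + 1, L + 1, L + 1, L + 1))
    for n in range(L + 1):
        Rn[n, 0, 0, 0] = (-2.0 * alpha) ** n * F[n]
    for n in range(L - 1, -1, -1):
        for t in range(L - n + 1):
            for u in range(L - n - t + 1):
                for v in range(L - n - t - u + 1):
                    if t + u + v == 0:
                        continue
                    if t > 0:
                        val = X * Rn[n + 1, t - 1, u, v]
                        if t > 1:
                            val += (t - 1) * Rn[n + 1, t - 2, u, v]
                    elif u > 0:
                        val = Y * Rn[n + 1, t, u - 1, v]
                        if u > 1:
                            val += (u - 1) * Rn[n + 1, t, u - 2, v]
                    else:
                        val = Z * Rn[n + 1, t, u, v - 1]
                        if v > 1:
                            val += (v - 1) * Rn[n + 1, t, u, v - 2]
                    Rn[n, t, u, v] = val
    R[: L + 1, : L + 1, : L + 1] = Rn[0, : L + 1, : L + 1, : L + 1]


@njit(cache=True)
def _one_electron(ls, centers, pstart, pcount, exps, coefs, offsets,
                  TR, CARTPOW, nsph, ncart, nbf, charges, chpos, do_kin):
    """Overlap, kinetic, and point-charge attraction matrices."""
    S = np.zeros((nbf, nbf))
    K = np.zeros((nbf, nbf))
    V = np.zeros((nbf, nbf))
    nsh = len(ls)
    Ex = np.zeros((_MAXL + 1, _MAXL + 3, 2 * _MAXL + 5))
    Ey = np.zeros_like(Ex)
    Ez = np.zeros_like(Ex)
    Rt = np.zeros((2 * _MAXL + 1, 2 * _MAXL + 1, 2 * _MAXL + 1))
    cS = np.zeros((6, 6))
    cK = np.zeros((6, 6))
    cV = np.zeros((6, 6))
    nch = len(charges)
    for ish in range(nsh):
        l1 = ls[ish]
        n1c = ncart[l1]
        n1s = nsph[l1]
        for jsh in range(ish + 1):
            l2 = ls[jsh]
            n2c = ncart[l2]
            n2s = nsph[l2]
            cS[:, :] = 0.0
            cK[:, :] = 0.0
            cV[:, :] = 0.0
            for ip in range(pcount[ish]):
                a = exps[pstart[ish] + ip]
                ca = coefs[pstart[ish] + ip]
                for jp in range(pcount[jsh]):
                    b = exps[pstart[jsh] + jp]
                    cb = coefs[pstart[jsh] + jp]
                    cc = ca * cb
                    p = a + b
                    # E with l2+2 for kinetic
                    _efill(l1, l2 + 2, centers[ish, 0], centers[jsh, 0], a, b, Ex)
                    _efill(l1, l2 + 2, centers[ish, 1], centers[jsh, 1], a, b, Ey)
                    _efill(l1, l2 + 2, centers[ish, 2], centers[jsh, 2], a, b, Ez)
                    sq = math.sqrt(math.pi / p)
                    Px = (a * centers[ish, 0] + b * centers[jsh, 0]) / p
                    Py = (a * centers[ish, 1] + b * centers[jsh, 1]) / p
                    Pz = (a * centers[ish, 2] + b * centers[jsh, 2]) / p
                    for c1 in range(n1c):
                        lx1 = CARTPOW[l1, c1, 0]
                        ly1 = CARTPOW[l1, c1, 1]
                        lz1 = CARTPOW[l1, c1, 2]
                        for c2 in range(n2c):
                            lx2 = CARTPOW[l2, c2, 0]
                            ly2 = CARTPOW[l2, c2, 1]
                            lz2 = CARTPOW[l2, c2, 2]
                            cS[c1, c2] += cc * sq ** 3 * Ex[lx1, lx2, 0] \
                                * Ey[ly1, ly2, 0] * Ez[lz1, lz2, 0]
                    if do_kin:
                        # -1/2 Laplacian via raised/lowered 1D overlaps
                        for c1 in range(n1c):
                            lx1 = CARTPOW[l1, c1, 0]
                            ly1 = CARTPOW[l1, c1, 1]
                            lz1 = CARTPOW[l1, c1, 2]
                            for c2 in range(n2c):
                                lx2 = CARTPOW[l2, c2, 0]
                                ly2 = CARTPOW[l2, c2, 1]
                                lz2 = CARTPOW[l2, c2, 2]
                                sx = Ex[lx1, lx2, 0]
                                sy = Ey[ly1, ly2, 0]
                                sz = Ez[lz1, lz2, 0]
                                kx = -2.0 * b * b * Ex[lx1, lx2 + 2, 0] \
                                    + b * (2 * lx2 + 1) * sx
                                if lx2 >= 2:
                                    kx -= 0.5 * lx2 * (lx2 - 1) * Ex[lx1, lx2 - 2, 0]
                                ky = -2.0 * b * b * Ey[ly1, ly2 + 2, 0] \
                                    + b * (2 * ly2 + 1) * sy
                                if ly2 >= 2:
                                    ky -= 0.5 * ly2 * (ly2 - 1) * Ey[ly1, ly2 - 2, 0]
                                kz = -2.0 * b * b * Ez[lz1, lz2 + 2, 0] \
                                    + b * (2 * lz2 + 1) * sz
                                if lz2 >= 2:
                                    kz -= 0.5 * lz2 * (lz2 - 1) * Ez[lz1, lz2 - 2, 0]
                                cK[c1, c2] += cc * sq * sq * sq * \
                                    (kx * sy * sz + sx * ky * sz + sx * sy * kz)
                    # nuclear attraction
                    if nch > 0:
                        L = l1 + l2
                        for ich in range(nch):
                            Xpc = Px - chpos[ich, 0]
                            Ypc = Py - chpos[ich, 1]
                            Zpc = Pz - chpos[ich, 2]
                            T = p * (Xpc * Xpc + Ypc * Ypc + Zpc * Zpc)
                            _rfill(L, p, Xpc, Ypc, Zpc, T, Rt)
                            pref = -charges[ich] * 2.0 * math.pi / p * cc
                            for c1 in range(n1c):
                                lx1 = CARTPOW[l1, c1, 0]
                                ly1 = CARTPOW[l1, c1, 1]
                                lz1 = CARTPOW[l1, c1, 2]
                                for c2 in range(n2c):
                                    lx2 = CARTPOW[l2, c2, 0]
                                    ly2 = CARTPOW[l2, c2, 1]
                                    lz2 = CARTPOW[l2, c2, 2]
                                    acc = 0.0
                                    for t in range(lx1 + lx2 + 1):
                                        ex = Ex[lx1, lx2, t]
                                        for u in range(ly1 + ly2 + 1):
                                            ey = Ey[ly1, ly2, u]
                                            for v in range(lz1 + lz2 + 1):
                                                acc += ex * ey * Ez[lz1, lz2, v] \
                                                    * Rt[t, u, v]
                                    cV[c1, c2] += pref * acc
            # cart -> sph and scatter
            o1 = offsets[ish]
            o2 = offsets[jsh]
            for m1 in range(n1s):
                for m2 in range(n2s):
                    vs = 0.0
                    vk = 0.0
                    vv = 0.0
                    for c1 in range(n1c):
                        w1 = TR[l1, m1, c1]
                        if w1 == 0.0:
                            continue
                        for c2 in range(n2c):
                            w2 = TR[l2, m2, c2]
                            if w2 == 0.0:
                                continue
                            vs += w1 * w2 * cS[c1, c2]
                            vk += w1 * w2 * cK[c1, c2]
                            vv += w1 * w2 * cV[c1, c2]
                    S[o1 + m1, o2 + m2] = vs
                    S[o2 + m2, o1 + m1] = vs
                    K[o1 + m1, o2 + m2] = vk
                    K[o2 + m2, o1 + m1] = vk
                    V[o1 + m1, o2 + m2] = vv
                    V[o2 + m2, o1 + m1] = vv
    return S, K, V


@njit(cache=True)
def _eri_kernel(ls, centers, pstart, pcount, exps, coefs, offsets,
                TR, CARTPOW, nsph, ncart, nbf):
    out = np.zeros((nbf, nbf, nbf, nbf))
    nsh = len(ls)
    E1x = np.zeros((_MAXL + 1, _MAXL + 1, 2 * _MAXL + 1))
    E1y = np.zeros_like(E1x)
    E1z = np.zeros_like(E1x)
    E2x = np.zeros_like(E1x)
    E2y = np.zeros_like(E1x)
    E2z = np.zeros_like(E1x)
    LMAX = 4 * _MAXL
    Rt = np.zeros((LMAX + 1, LMAX + 1, LMAX + 1))
    nher = 2 * _MAXL + 1
    T1 = np.zeros((nher, nher, nher, 36))
    cblk = np.zeros((6, 6, 6, 6))
    sblk = np.zeros((5, 5, 5, 5))
    half = np.zeros((5, 5, 6, 6))
    pref0 = 2.0 * math.pi ** 2.5
    for ish in range(nsh):
        l1 = ls[ish]
        for jsh in range(ish + 1):
            l2 = ls[jsh]
            ij = ish * (ish + 1) // 2 + jsh
            for ksh in range(ish + 1):
                l3 = ls[ksh]
                for lsh in range(ksh + 1):
                    kl = ksh * (ksh + 1) // 2 + lsh
                    if kl > ij:
                        continue
                    l4 = ls[lsh]
                    n1c, n2c, n3c, n4c = ncart[l1], ncart[l2], ncart[l3], ncart[l4]
                    L = l1 + l2 + l3 + l4
                    cblk[:, :, :, :] = 0.0
                    for ip in range(pcount[ish]):
                        a = exps[pstart[ish] + ip]
                        ca = coefs[pstart[ish] + ip]
                        for jp in range(pcount[jsh]):
                            b = exps[pstart[jsh] + jp]
                            cab = ca * coefs[pstart[jsh] + jp]
                            p = a + b
                            Px = (a * centers[ish, 0] + b * centers[jsh, 0]) / p
                            Py = (a * centers[ish, 1] + b * centers[jsh, 1]) / p
                            Pz = (a * centers[ish, 2] + b * centers[jsh, 2]) / p
                            _efill(l1, l2, centers[ish, 0], centers[jsh, 0], a, b, E1x)
                            _efill(l1, l2, centers[ish, 1], centers[jsh, 1], a, b, E1y)
                            _efill(l1, l2, centers[ish, 2], centers[jsh, 2], a, b, E1z)
                            for kp in range(pcount[ksh]):
                                c = exps[pstart[ksh] + kp]
                                cc3 = coefs[pstart[ksh] + kp]
                                for lp in range(pcount[lsh]):
                                    d = exps[pstart[lsh] + lp]
                                    cfac = cab * cc3 * coefs[pstart[lsh] + lp]
                                    q = c + d
                                    Qx = (c * centers[ksh, 0] + d * centers[lsh, 0]) / q
                                    Qy = (c * centers[ksh, 1] + d * centers[lsh, 1]) / q
                                    Qz = (c * centers[ksh, 2] + d * centers[lsh, 2]) / q
                                    _efill(l3, l4, centers[ksh, 0], centers[lsh, 0],
                                           c, d, E2x)
                                    _efill(l3, l4, centers[ksh, 1], centers[lsh, 1],
                                           c, d, E2y)
                                    _efill(l3, l4, centers[ksh, 2], centers[lsh, 2],
                                           c, d, E2z)
                                    alpha = p * q / (p + q)
                                    Xpq = Px - Qx
                                    Ypq = Py - Qy
                                    Zpq = Pz - Qz
                                    T = alpha * (Xpq * Xpq + Ypq * Ypq + Zpq * Zpq)
                                    _rfill(L, alpha, Xpq, Ypq, Zpq, T, Rt)
                                    pref = pref0 / (p * q * math.sqrt(p + q)) * cfac
                                    nb1 = l1 + l2  # max bra hermite order / dim
                                    # step A: hermite-transform the ket side
                                    for c3 in range(n3c):
                                        lx3 = CARTPOW[l3, c3, 0]
                                        ly3 = CARTPOW[l3, c3, 1]
                                        lz3 = CARTPOW[l3, c3, 2]
                                        for c4 in range(n4c):
                                            lx4 = CARTPOW[l4, c4, 0]
                                            ly4 = CARTPOW[l4, c4, 1]
                                            lz4 = CARTPOW[l4, c4, 2]
                                            c34 = c3 * 6 + c4
                                            for t in range(nb1 + 1):
                                                for u in range(nb1 - t + 1):
                                                    for v in range(nb1 - t - u + 1):
                                                        s = 0.0
                                                        for tt in range(lx3 + lx4 + 1):
                                                            ex = E2x[lx3, lx4, tt]
                                                            for uu in range(ly3 + ly4 + 1):
                                                                exy = ex * E2y[ly3, ly4, uu]
                                                                for vv in range(lz3 + lz4 + 1):
                                                                    w = exy * E2z[lz3, lz4, vv]
                                                                    if (tt + uu + vv) % 2 == 1:
                                                                        w = -w
                                                                    s += w * Rt[t + tt, u + uu, v + vv]
                                                        T1[t, u, v, c34] = s
                                    # step B: bra contraction
                                    for c1 in range(n1c):
                                        lx1 = CARTPOW[l1, c1, 0]
                                        ly1 = CARTPOW[l1, c1, 1]
                                        lz1 = CARTPOW[l1, c1, 2]
                                        for c2 in range(n2c):
                                            lx2 = CARTPOW[l2, c2, 0]
                                            ly2 = CARTPOW[l2, c2, 1]
                                            lz2 = CARTPOW[l2, c2, 2]
                                            for c3 in range(n3c):
                                                for c4 in range(n4c):
                                                    c34 = c3 * 6 + c4
                                                    s = 0.0
                                                    for t in range(lx1 + lx2 + 1):
                                                        ex = E1x[lx1, lx2, t]
                                                        for u in range(ly1 + ly2 + 1):
                                                            exy = ex * E1y[ly1, ly2, u]
                                                            for v in range(lz1 + lz2 + 1):
                                                                s += exy * E1z[lz1, lz2, v] \
                                                                    * T1[t, u, v, c34]
                                                    cblk[c1, c2, c3, c4] += pref * s
                    # cartesian -> spherical on all four indices
                    n1s, n2s, n3s, n4s = nsph[l1], nsph[l2], nsph[l3], nsph[l4]
                    for m1 in range(n1s):
                        for m2 in range(n2s):
                            for c3 in range(n3c):
                                for c4 in range(n4c):
                                    s = 0.0
                                    for c1 in range(n1c):
                                        w1 = TR[l1, m1, c1]
                                        if w1 == 0.0:
                                            continue
                                        for c2 in range(n2c):
                                            w2 = TR[l2, m2, c2]
                                            if w2 != 0.0:
                                                s += w1 * w2 * cblk[c1, c2, c3, c4]
                                    half[m1, m2, c3, c4] = s
                    for m1 in range(n1s):
                        for m2 in range(n2s):
                            for m3 in range(n3s):
                                for m4 in range(n4s):
                                    s = 0.0
                                    for c3 in range(n3c):
                                        w3 = TR[l3, m3, c3]
                                        if w3 == 0.0:
                                            continue
                                        for c4 in range(n4c):
                                            w4 = TR[l4, m4, c4]
                                            if w4 != 0.0:
                                                s += w3 * w4 * half[m1, m2, c3, c4]
                                    sblk[m1, m2, m3, m4] = s
                    o1, o2, o3, o4 = offsets[ish], offsets[jsh], offsets[ksh], offsets[lsh]
                    for m1 in range(n1s):
                        for m2 in range(n2s):
                            for m3 in range(n3s):
                                for m4 in range(n4s):
                                    vv = sblk[m1, m2, m3, m4]
                                    i1, i2, i3, i4 = o1 + m1, o2 + m2, o3 + m3, o4 + m4
                                    out[i1, i2, i3, i4] = vv
                                    out[i2, i1, i3, i4] = vv
                                    out[i1, i2, i4, i3] = vv
                                    out[i2, i1, i4, i3] = vv
                                    out[i3, i4, i1, i2] = vv
                                    out[i4, i3, i1, i2] = vv
                                    out[i3, i4, i2, i1] = vv
                                    out[i4, i3, i2, i1] = vv
    return out


class AOIntegrals:
    """One- and two-electron integrals over a spherical Gaussian basis.

    Matrices are normalized so that the overlap diagonal is exactly 1.
    ``eri`` is stored in chemists' notation (pq|rs).
    """

    def __init__(self, basis: BasisSet, with_eri: bool = True):
        self.basis = basis
        ls, centers, pstart, pcount, exps, coefs = basis.flat_arrays()
        offsets = basis.shell_offsets()
        nbf = basis.n_functions
        mol = basis.molecule
        charges = mol.charges
        chpos = mol.coords if len(mol.atoms) else np.zeros((0, 3))
        live = charges != 0.0
        S, K, V = _one_electron(ls, centers, pstart, pcount, exps, coefs,
                                offsets, _TR, _CARTPOW, _NSPH, _NCART, nbf,
                                charges[live], chpos[live], True)
        norm = 1.0 / np.sqrt(np.diag(S))
        self.norm = norm
        nn = np.outer(norm, norm)
        self.S = S * nn
        self.T = K * nn
        self.V = V * nn
        self.hcore = self.T + self.V
        self.nuclear_repulsion = mol.nuclear_repulsion()
        self.eri = None
        if with_eri:
            eri = _eri_kernel(ls, centers, pstart, pcount, exps, coefs,
                              offsets, _TR, _CARTPOW, _NSPH, _NCART, nbf)
            eri *= norm[:, None, None, None]
            eri *= norm[None, :, None, None]
            eri *= norm[None, None, :, None]
            eri *= norm[None, None, None, :]
            self.eri = eri
        self._flat = (ls, centers, pstart, pcount, exps, coefs, offsets, nbf)

    def point_charge_potential(self, charges, positions) -> np.ndarray:
        """Attraction matrix for an arbitrary set of point charges."""
        ls, centers, pstart, pcount, exps, coefs, offsets, nbf = self._flat
        charges = np.asarray(charges, float)
        positions = np.asarray(positions, float).reshape(-1, 3)
        _, _, V = _one_electron(ls, centers, pstart, pcount, exps, coefs,
                                offsets, _TR, _CARTPOW, _NSPH, _NCART, nbf,
                                charges, positions, False)
        return V * np.outer(self.norm, self.norm)

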