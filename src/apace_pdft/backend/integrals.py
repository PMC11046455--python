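"""One- and two-electron integrals over contracted Cartesian Gaussians.

McMurchie–Davidson scheme: Hermite expansion coefficients E for overlap-type
integrals, Hermite Coulomb tensor R (via the Boys function) for nuclear
attraction and electron repulsion.  Kernels are numba-compiled; the public
functions take a :class:`~.basis.BasisSet` and return dense numpy arrays.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# ---------------------------------------------------------------- Boys


@njit(cache=True)
def _boys(t: float, mmax: int, out: np.ndarray) -> None:
    """Fill out[0:mmax+1] with F_m(t)."""
    if t < 1e-13:
        for m in range(mmax + 1):
            out[m] = 1.0 / (2 * m + 1) - t / (2 * m + 3)
        return
    if t > 35.0:
        out[0] = 0.5 * np.sqrt(np.pi / t)
        emt = np.exp(-t)
        for m in range(mmax):
            out[m + 1] = ((2 * m + 1) * out[m] - emt) / (2 * t)
        return
    # series at the highest order, downward recursion below
    emt = np.exp(-t)
    term = 1.0 / (2 * mmax + 1)
    s = term
    i = 1
    while True:
        term *= 2 * t / (2 * mmax + 2 * i + 1)
        s += term
        if term < 1e-17 * s or i > 200:
            break
        i += 1
    out[mmax] = emt * s
    for m in range(mmax - 1, -1, -1):
        out[m] = (2 * t * out[m + 1] + emt) / (2 * m + 1)


# ---------------------------------------------------------------- E and R


@njit(cache=True)
def _e_table(l1: int, l2: int, a: float, b: float, ab: float, etab: np.ndarray) -> None:
    """Hermite expansion coefficients E[i,j,t] for one Cartesian direction.

    ab = A_x - B_x.  etab must be zeroed, shape >= (l1+1, l2+1, l1+l2+1).
    """
    p = a + b
    mu = a * b / p
    etab[0, 0, 0] = np.exp(-mu * ab * ab)
    pa = -b * ab / p  # P - A
    pb = a * ab / p  # P - B  (P - B = a/p * (A - B) ... sign: P = (aA+bB)/p)
    # fill increasing i then j
    for i in range(l1):
        for t in range(i + 2):
            v = pa * etab[i, 0, t]
            if t > 0:
                v += etab[i, 0, t - 1] / (2 * p)
            if t + 1 <= i:
                v += (t + 1) * etab[i, 0, t + 1]
            etab[i + 1, 0, t] = v
    for i in range(l1 + 1):
        for j in range(l2):
            for t in range(i + j + 2):
                v = pb * etab[i, j, t]
                if t > 0:
                    v += etab[i, j, t - 1] / (2 * p)
                if t + 1 <= i + j:
                    v += (t + 1) * etab[i, j, t + 1]
                etab[i, j + 1, t] = v


@njit(cache=True)
def _r_tensor(lmax: int, alpha: float, x: float, y: float, z: float,
              rtab: np.ndarray, fbuf: np.ndarray) -> None:
    """Hermite Coulomb integrals R[t,u,v] (n=0 slice of the auxiliary set)."""
    t2 = alpha * (x * x + y * y + z * z)
    _boys(t2, lmax, fbuf)
    # rtab shape (lmax+1, lmax+1, lmax+1, lmax+1): [n, t, u, v]
    rtab[:, :, :, :] = 0.0
    for n in range(lmax + 1):
        rtab[n, 0, 0, 0] = (-2.0 * alpha) ** n * fbuf[n]
    for n in range(lmax - 1, -1, -1):
        for t in range(lmax - n + 1):
            for u in range(lmax - n - t + 1):
                for v in range(lmax - n - t - u + 1):
                    if t + u + v == 0:
                        continue
                    if t > 0:
                        val = x * rtab[n + 1, t - 1, u, v]
                        if t > 1:
                            val += (t - 1) * rtab[n + 1, t - 2, u, v]
                    elif u > 0:
                        val = y * rtab[n + 1, t, u - 1, v]
                        if u > 1:
                            val += (u - 1) * rtab[n + 1, t, u - 2, v]
                    else:
                        val = z * rtab[n + 1, t, u, v - 1]
                        if v > 1:
                            val += (v - 1) * rtab[n + 1, t, u, v - 2]
                    rtab[n, t, u, v] = val


# ---------------------------------------------------------------- one-electron


@njit(cache=True)
def _overlap_kinetic_kernel(ang, center, exps, coefs, nprim, lmax):
    nao = ang.shape[0]
    s = np.zeros((nao, nao))
    t = np.zeros((nao, nao))
    dim1 = lmax + 1
    dim2 = lmax + 3  # kinetic needs l2+2
    et = np.zeros((3, dim1, dim2, dim1 + dim2))
    for mu in range(nao):
        for nu in range(mu + 1):
            sv = 0.0
            tv = 0.0
            for ip in range(nprim[mu]):
                a = exps[mu, ip]
                ca = coefs[mu, ip]
                for jp in range(nprim[nu]):
                    b = exps[nu, jp]
                    cb = coefs[nu, jp]
                    p = a + b
                    pref = ca * cb * (np.pi / p) ** 1.5
                    s1 = np.zeros(3)
                    s_p2 = np.zeros(3)  # ⟨i|j+2⟩
                    s_m2 = np.zeros(3)  # ⟨i|j-2⟩
                    for d in range(3):
                        l1 = ang[mu, d]
                        l2 = ang[nu, d]
                        et[d, :, :, :] = 0.0
                        _e_table(l1, l2 + 2, a, b, center[mu, d] - center[nu, d], et[d])
                        s1[d] = et[d, l1, l2, 0]
                        s_p2[d] = et[d, l1, l2 + 2, 0]
                        s_m2[d] = et[d, l1, l2 - 2, 0] if l2 >= 2 else 0.0
                    sv += pref * s1[0] * s1[1] * s1[2]
                    for d in range(3):
                        l2 = ang[nu, d]
                        t1d = (-2.0 * b * b * s_p2[d]
                               + b * (2 * l2 + 1) * s1[d]
                               - 0.5 * l2 * (l2 - 1) * s_m2[d])
                        o1 = s1[(d + 1) % 3]
                        o2 = s1[(d + 2) % 3]
                        tv += pref * t1d * o1 * o2
            s[mu, nu] = sv
            s[nu, mu] = sv
            t[mu, nu] = tv
            t[nu, mu] = tv
    return s, t


@njit(cache=True)
def _nuclear_kernel(ang, center, exps, coefs, nprim, lmax, lsum, atom_coords, atom_z):
    nao = ang.shape[0]
    v = np.zeros((nao, nao))
    dim = lmax + 1
    et = np.zeros((3, dim, dim, 2 * dim))
    ltot_max = 2 * lsum
    rtab = np.zeros((ltot_max + 1, ltot_max + 1, ltot_max + 1, ltot_max + 1))
    fbuf = np.zeros(ltot_max + 1)
    natm = atom_coords.shape[0]
    for mu in range(nao):
        for nu in range(mu + 1):
            acc = 0.0
            for ip in range(nprim[mu]):
                a = exps[mu, ip]
                ca = coefs[mu, ip]
                for jp in range(nprim[nu]):
                    b = exps[nu, jp]
                    cb = coefs[nu, jp]
                    p = a + b
                    px = (a * center[mu, 0] + b * center[nu, 0]) / p
                    py = (a * center[mu, 1] + b * center[nu, 1]) / p
                    pz = (a * center[mu, 2] + b * center[nu, 2]) / p
                    for d in range(3):
                        et[d, :, :, :] = 0.0
                        _e_table(ang[mu, d], ang[nu, d], a, b,
                                 center[mu, d] - center[nu, d], et[d])
                    ltot = (ang[mu, 0] + ang[mu, 1] + ang[mu, 2]
                            + ang[nu, 0] + ang[nu, 1] + ang[nu, 2])
                    pref = ca * cb * 2.0 * np.pi / p
                    for iatm in range(natm):
                        _r_tensor(ltot, p,
                                  px - atom_coords[iatm, 0],
                                  py - atom_coords[iatm, 1],
                                  pz - atom_coords[iatm, 2], rtab, fbuf)
                        val = 0.0
                        for t in range(ang[mu, 0] + ang[nu, 0] + 1):
                            for u in range(ang[mu, 1] + ang[nu, 1] + 1):
                                for w in range(ang[mu, 2] + ang[nu, 2] + 1):
                                    val += (et[0, ang[mu, 0], ang[nu, 0], t]
                                            * et[1, ang[mu, 1], ang[nu, 1], u]
                                            * et[2, ang[mu, 2], ang[nu, 2], w]
                                            * rtab[0, t, u, w])
                        acc -= atom_z[iatm] * pref * val
            v[mu, nu] = acc
            v[nu, mu] = acc
    return v


# ---------------------------------------------------------------- ERI


@njit(cache=True)
def _eri_kernel(ang, center, exps, coefs, nprim, lmax, lsum):
    nao = ang.shape[0]
    eri = np.zeros((nao, nao, nao, nao))
    dim = lmax + 1
    etb = np.zeros((3, dim, dim, 2 * dim))
    etk = np.zeros((3, dim, dim, 2 * dim))
    ltot_max = 4 * lsum
    rtab = np.zeros((ltot_max + 1, ltot_max + 1, ltot_max + 1, ltot_max + 1))
    fbuf = np.zeros(ltot_max + 1)
    tpf = 2.0 * np.pi ** 2.5
    for mu in range(nao):
        for nu in range(mu + 1):
            lb = (ang[mu, 0] + ang[mu, 1] + ang[mu, 2]
                  + ang[nu, 0] + ang[nu, 1] + ang[nu, 2])
            for lam in range(mu + 1):
                sig_max = nu if lam == mu else lam
                for sig in range(sig_max + 1):
                    lk = (ang[lam, 0] + ang[lam, 1] + ang[lam, 2]
                          + ang[sig, 0] + ang[sig, 1] + ang[sig, 2])
                    acc = 0.0
                    for ip in range(nprim[mu]):
                        a = exps[mu, ip]
                        ca = coefs[mu, ip]
                        for jp in range(nprim[nu]):
                            b = exps[nu, jp]
                            cb = coefs[nu, jp]
                            p = a + b
                            px = (a * center[mu, 0] + b * center[nu, 0]) / p
                            py = (a * center[mu, 1] + b * center[nu, 1]) / p
                            pz = (a * center[mu, 2] + b * center[nu, 2]) / p
                            for d in range(3):
                                etb[d, :, :, :] = 0.0
                                _e_table(ang[mu, d], ang[nu, d], a, b,
                                         center[mu, d] - center[nu, d], etb[d])
                            for kp in range(nprim[lam]):
                                c = exps[lam, kp]
                                cc = coefs[lam, kp]
                                for lp in range(nprim[sig]):
                                    dd = exps[sig, lp]
                                    cd = coefs[sig, lp]
                                    q = c + dd
                                    qx = (c * center[lam, 0] + dd * center[sig, 0]) / q
                                    qy = (c * center[lam, 1] + dd * center[sig, 1]) / q
                                    qz = (c * center[lam, 2] + dd * center[sig, 2]) / q
                                    for d in range(3):
                                        etk[d, :, :, :] = 0.0
                                        _e_table(ang[lam, d], ang[sig, d], c, dd,
                                                 center[lam, d] - center[sig, d],
                                                 etk[d])
                                    alpha = p * q / (p + q)
                                    _r_tensor(lb + lk, alpha,
                                              px - qx, py - qy, pz - qz, rtab, fbuf)
                                    pref = (ca * cb * cc * cd * tpf
                                            / (p * q * np.sqrt(p + q)))
                                    val = 0.0
                                    for t in range(ang[mu, 0] + ang[nu, 0] + 1):
                                        for u in range(ang[mu, 1] + ang[nu, 1] + 1):
                                            for w in range(ang[mu, 2] + ang[nu, 2] + 1):
                                                eb = (etb[0, ang[mu, 0], ang[nu, 0], t]
                                                      * etb[1, ang[mu, 1], ang[nu, 1], u]
                                                      * etb[2, ang[mu, 2], ang[nu, 2], w])
                                                if eb == 0.0:
                                                    continue
                                                for tt in range(ang[lam, 0] + ang[sig, 0] + 1):
                                                    for uu in range(ang[lam, 1] + ang[sig, 1] + 1):
                                                        for ww in range(ang[lam, 2] + ang[sig, 2] + 1):
                                                            ek = (etk[0, ang[lam, 0], ang[sig, 0], tt]
                                                                  * etk[1, ang[lam, 1], ang[sig, 1], uu]
                                                                  * etk[2, ang[lam, 2], ang[sig, 2], ww])
                                                            if ek == 0.0:
                                                                continue
                                                            sign = 1.0 if (tt + uu + ww) % 2 == 0 else -1.0
                                                            val += eb * ek * sign * rtab[0, t + tt, u + uu, w + ww]
                                    acc += pref * val
                    eri[mu, nu, lam, sig] = acc
                    eri[nu, mu, lam, sig] = acc
                    eri[mu, nu, sig, lam] = acc
                    eri[nu, mu, sig, lam] = acc
                    eri[lam, sig, mu, nu] = acc
                    eri[sig, lam, mu, nu] = acc
                    eri[lam, sig, nu, mu] = acc
                    eri[sig, lam, nu, mu] = acc
    return eri


# ---------------------------------------------------------------- public API


def overlap_matrix(bs) -> np.ndarray:
    lmax = int(bs.ang.max())
    s, _ = _overlap_kinetic_kernel(bs.ang, bs.center, bs.exps, bs.coefs, bs.nprim, lmax)
    return s


def kinetic_matrix(bs) -> np.ndarray:
    lmax = int(bs.ang.max())
    _, t = _overlap_kinetic_kernel(bs.ang, bs.center, bs.exps, bs.coefs, bs.nprim, lmax)
    return t


def nuclear_attraction_matrix(bs, atom_coords_bohr: np.ndarray, atom_z: np.ndarray) -> np.ndarray:
    lmax = int(bs.ang.max())
    lsum = int(bs.ang.sum(axis=1).max())
    return _nuclear_kernel(bs.ang, bs.center, bs.exps, bs.coefs, bs.nprim, lmax, lsum,
                           np.asarray(atom_coords_bohr, float),
                           np.asarray(atom_z, float))


def eri_tensor(bs) -> np.ndarray:
    """Full (μν|λσ) tensor in chemist notation."""
    lmax = int(bs.ang.max())
    lsum = int(bs.ang.sum(axis=1).max())
    return _eri_kernel(bs.ang, bs.center, bs.exps, bs.coefs, bs.nprim, lmax, lsum)
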