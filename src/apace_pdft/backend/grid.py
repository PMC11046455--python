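"""Molecular quadrature grid: Becke partitioning of atom-centered grids.

Radial: Gauss–Chebyshev (second kind) mapped to (0, ∞) with the rational
map r = R (1+x)/(1−x).  Angular: Gauss–Legendre in cos θ × uniform φ, which
integrates spherical harmonics exactly up to degree ~2 n_θ − 1.  Atomic
cells are blended with Becke's thrice-iterated smoothing polynomial (no
atomic-size adjustment).  AO values and Cartesian first derivatives are
tabulated on the grid for density and GGA work.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .basis import BasisSet, build_basis
from .molecule import Molecule

#: level -> (n_radial, n_theta); n_phi = 2 n_theta
_LEVELS = {
    0: (35, 10),
    1: (50, 14),
    2: (75, 18),
    3: (100, 24),
    4: (140, 30),
}
DEFAULT_LEVEL = 2


@dataclass
class QuadratureGrid:
    points: np.ndarray  # (npts, 3) bohr
    weights: np.ndarray  # (npts,)
    ao_values: np.ndarray  # (npts, nao)
    ao_gradients: np.ndarray  # (npts, 3, nao)
    basis: BasisSet = field(repr=False, default=None)
    level: int = DEFAULT_LEVEL

    @property
    def n_points(self) -> int:
        return len(self.weights)


def _radial(n: int, scale: float) -> tuple[np.ndarray, np.ndarray]:
    i = np.arange(1, n + 1)
    x = np.cos(i * np.pi / (n + 1))
    w_cheb = np.pi / (n + 1) * np.sin(i * np.pi / (n + 1)) ** 2
    r = scale * (1.0 + x) / (1.0 - x)
    # dr/dx = 2 scale / (1-x)^2 ; Chebyshev weight already carries sqrt(1-x^2)
    dr = 2.0 * scale / (1.0 - x) ** 2
    w = w_cheb / np.sqrt(1.0 - x**2) * dr * r**2
    return r, w


def _angular(n_theta: int) -> tuple[np.ndarray, np.ndarray]:
    ct, wt = np.polynomial.legendre.leggauss(n_theta)
    st = np.sqrt(1.0 - ct**2)
    n_phi = 2 * n_theta
    phi = 2.0 * np.pi * np.arange(n_phi) / n_phi
    wp = 2.0 * np.pi / n_phi
    dirs = np.empty((n_theta * n_phi, 3))
    wang = np.empty(n_theta * n_phi)
    k = 0
    for it in range(n_theta):
        for ip in range(n_phi):
            dirs[k] = (st[it] * np.cos(phi[ip]), st[it] * np.sin(phi[ip]), ct[it])
            wang[k] = wt[it] * wp
            k += 1
    return dirs, wang


@njit(cache=True)
def _becke_weights_kernel(points, atoms, iatom):
    natm = atoms.shape[0]
    npts = points.shape[0]
    out = np.empty(npts)
    dists = np.empty(natm)
    cell = np.empty(natm)
    for ip in range(npts):
        for a in range(natm):
            dx = points[ip, 0] - atoms[a, 0]
            dy = points[ip, 1] - atoms[a, 1]
            dz = points[ip, 2] - atoms[a, 2]
            dists[a] = np.sqrt(dx * dx + dy * dy + dz * dz)
        for a in range(natm):
            cell[a] = 1.0
        for a in range(natm):
            for b in range(a + 1, natm):
                dx = atoms[a, 0] - atoms[b, 0]
                dy = atoms[a, 1] - atoms[b, 1]
                dz = atoms[a, 2] - atoms[b, 2]
                rab = np.sqrt(dx * dx + dy * dy + dz * dz)
                mu = (dists[a] - dists[b]) / rab
                for _ in range(3):
                    mu = 1.5 * mu - 0.5 * mu**3
                cell[a] *= 0.5 * (1.0 - mu)
                cell[b] *= 0.5 * (1.0 + mu)
        tot = 0.0
        for a in range(natm):
            tot += cell[a]
        out[ip] = cell[iatom] / tot if tot > 0.0 else 0.0
    return out


def _becke_weights(points: np.ndarray, atoms: np.ndarray, iatom: int) -> np.ndarray:
    if len(atoms) == 1:
        return np.ones(len(points))
    return _becke_weights_kernel(
        np.ascontiguousarray(points), np.ascontiguousarray(atoms), iatom
    )


@njit(cache=True)
def _ao_kernel(ang, center, exps, coefs, nprim, points, vals, grads):
    npts = points.shape[0]
    nao = ang.shape[0]
    for ip in range(npts):
        for mu in range(nao):
            dx = points[ip, 0] - center[mu, 0]
            dy = points[ip, 1] - center[mu, 1]
            dz = points[ip, 2] - center[mu, 2]
            r2 = dx * dx + dy * dy + dz * dz
            val = 0.0
            drad = 0.0
            for k in range(nprim[mu]):
                g = coefs[mu, k] * np.exp(-exps[mu, k] * r2)
                val += g
                drad += -2.0 * exps[mu, k] * g
            lx, ly, lz = ang[mu, 0], ang[mu, 1], ang[mu, 2]
            px = dx**lx
            py = dy**ly
            pz = dz**lz
            poly = px * py * pz
            vals[ip, mu] = poly * val
            # d/dx [x^l f(r)] = l x^{l-1} f + x^l (df/dr)(x/r)·r ...
            dpx = lx * dx ** (lx - 1) if lx > 0 else 0.0
            dpy = ly * dy ** (ly - 1) if ly > 0 else 0.0
            dpz = lz * dz ** (lz - 1) if lz > 0 else 0.0
            grads[ip, 0, mu] = dpx * py * pz * val + poly * dx * drad
            grads[ip, 1, mu] = px * dpy * pz * val + poly * dy * drad
            grads[ip, 2, mu] = px * py * dpz * val + poly * dz * drad


def evaluate_aos(bs: BasisSet, points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """AO values (npts, nao) and gradients (npts, 3, nao) at points (bohr)."""
    points = np.ascontiguousarray(points, dtype=float)
    vals = np.zeros((len(points), bs.nao))
    grads = np.zeros((len(points), 3, bs.nao))
    _ao_kernel(bs.ang, bs.center, bs.exps, bs.coefs, bs.nprim, points, vals, grads)
    return vals, grads


def build_grid(
    molecule: Molecule,
    basis: str | BasisSet,
    level: int = DEFAULT_LEVEL,
) -> QuadratureGrid:
    """Molecular Becke grid with AO values/gradients tabulated."""
    if level not in _LEVELS:
        raise ValueError(f"grid level must be one of {sorted(_LEVELS)}")
    bs = basis if isinstance(basis, BasisSet) else build_basis(molecule, basis)
    n_rad, n_theta = _LEVELS[level]
    dirs, wang = _angular(n_theta)
    atoms = molecule.coords_bohr
    all_pts, all_w = [], []
    for ia, center in enumerate(atoms):
        r, wr = _radial(n_rad, scale=1.0)
        pts = center[None, None, :] + r[:, None, None] * dirs[None, :, :]
        pts = pts.reshape(-1, 3)
        w = (wr[:, None] * wang[None, :]).reshape(-1)
        w = w * _becke_weights(pts, atoms, ia)
        keep = w > 1e-16
        all_pts.append(pts[keep])
        all_w.append(w[keep])
    points = np.concatenate(all_pts)
    weights = np.concatenate(all_w)
    vals, grads = evaluate_aos(bs, points)
    return QuadratureGrid(
        points=points, weights=weights, ao_values=vals, ao_gradients=grads,
        basis=bs, level=level,
    )
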