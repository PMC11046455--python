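"""Gaussian basis-set library and AO construction.

Shipped sets:

* ``sto-3g`` for H–Ne, generated from the classic three-Gaussian fits to
  Slater orbitals with the standard per-element zeta exponents (the scaled
  exponents reproduce the published STO-3G tables to their printed digits).
* ``cc-pvdz`` for hydrogen (the (4s1p)→[2s1p] set).

Cartesian Gaussians are used throughout (6 components per d shell).  Every
contracted AO is normalized numerically against its own analytic self-overlap,
which makes the stored contraction-coefficient convention irrelevant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .molecule import Molecule

# -- STO-3G: 3-Gaussian expansions of 1s/2s/2p Slater functions (zeta = 1) --
_STO3G_1S_EXP = np.array([2.227660584, 0.4057711562, 0.1098175104])
_STO3G_1S_COEF = np.array([0.1543289673, 0.5353281423, 0.4446345422])
_STO3G_2SP_EXP = np.array([0.9942030000, 0.2310313000, 0.0751386000])
_STO3G_2S_COEF = np.array([-0.0999672292, 0.3995128261, 0.7001154689])
_STO3G_2P_COEF = np.array([0.1559162750, 0.6076837186, 0.3919573931])

# per-element Slater exponents (zeta_1s, zeta_2sp)
_STO3G_ZETA = {
    "H": (1.24, None),
    "He": (1.69, None),
    "Li": (2.69, 0.80),
    "Be": (3.68, 1.15),
    "B": (4.68, 1.45),
    "C": (5.67, 1.72),
    "N": (6.67, 1.95),
    "O": (7.66, 2.25),
    "F": (8.65, 2.55),
    "Ne": (9.64, 2.88),
}

# -- cc-pVDZ hydrogen --
_CCPVDZ_H_S_EXP = np.array([13.0100, 1.9620, 0.4446, 0.1220])
_CCPVDZ_H_S_COEF = np.array([0.0196850, 0.1379770, 0.4781480, 0.5012400])
_CCPVDZ_H_S2_EXP = np.array([0.1220])
_CCPVDZ_H_S2_COEF = np.array([1.0])
_CCPVDZ_H_P_EXP = np.array([0.7270])
_CCPVDZ_H_P_COEF = np.array([1.0])


def _shells_for(element: str, basis: str) -> list[tuple[int, np.ndarray, np.ndarray]]:
    """Return a list of (l, exponents, coefficients) shells."""
    b = basis.lower().replace("_", "-")
    if b == "sto-3g":
        if element not in _STO3G_ZETA:
            raise ValueError(f"sto-3g not available for element {element}")
        z1, z2 = _STO3G_ZETA[element]
        shells = [(0, _STO3G_1S_EXP * z1**2, _STO3G_1S_COEF.copy())]
        if z2 is not None:
            shells.append((0, _STO3G_2SP_EXP * z2**2, _STO3G_2S_COEF.copy()))
            shells.append((1, _STO3G_2SP_EXP * z2**2, _STO3G_2P_COEF.copy()))
        return shells
    if b == "cc-pvdz":
        if element == "H":
            return [
                (0, _CCPVDZ_H_S_EXP, _CCPVDZ_H_S_COEF),
                (0, _CCPVDZ_H_S2_EXP, _CCPVDZ_H_S2_COEF),
                (1, _CCPVDZ_H_P_EXP, _CCPVDZ_H_P_COEF),
            ]
        raise ValueError(
            f"cc-pvdz is shipped for H only (requested {element}); "
            "use sto-3g for heavier elements"
        )
    raise ValueError(f"unknown basis set {basis!r}")


def _cartesian_components(l: int) -> list[tuple[int, int, int]]:
    return [
        (lx, ly, l - lx - ly)
        for lx in range(l, -1, -1)
        for ly in range(l - lx, -1, -1)
    ]


@dataclass
class BasisSet:
    """Contracted Cartesian Gaussian AOs for a molecule.

    Flat per-AO arrays sized for the numba integral kernels:
    ``ang`` (nao,3) Cartesian powers, ``center`` (nao,3) in bohr,
    ``exps``/``coefs`` (nao, max_prim) zero padded, ``nprim`` (nao,).
    """

    name: str
    ang: np.ndarray
    center: np.ndarray
    exps: np.ndarray
    coefs: np.ndarray
    nprim: np.ndarray
    shell_of_ao: np.ndarray

    @property
    def nao(self) -> int:
        return len(self.nprim)


def build_basis(molecule: Molecule, basis: str) -> BasisSet:
    ang, centers, exps, coefs, nprim, shell_ids = [], [], [], [], [], []
    coords = molecule.coords_bohr
    shell_counter = 0
    for atom, xyz in zip(molecule.elements, coords):
        for l, e, c in _shells_for(atom, basis):
            # primitive normalization for the (l,0,0) component; per-AO
            # numeric renormalization below fixes the remaining factors
            for lx, ly, lz in _cartesian_components(l):
                ang.append((lx, ly, lz))
                centers.append(xyz)
                norm = (2 * e / np.pi) ** 0.75 * (4 * e) ** (l / 2.0)
                exps.append(e)
                coefs.append(c * norm)
                nprim.append(len(e))
                shell_ids.append(shell_counter)
            shell_counter += 1
    max_prim = max(len(e) for e in exps)
    nao = len(ang)
    exp_arr = np.zeros((nao, max_prim))
    coef_arr = np.zeros((nao, max_prim))
    for i in range(nao):
        exp_arr[i, : nprim[i]] = exps[i]
        coef_arr[i, : nprim[i]] = coefs[i]
    bs = BasisSet(
        name=basis.lower(),
        ang=np.array(ang, dtype=np.int64),
        center=np.array(centers),
        exps=exp_arr,
        coefs=coef_arr,
        nprim=np.array(nprim, dtype=np.int64),
        shell_of_ao=np.array(shell_ids, dtype=np.int64),
    )
    _renormalize(bs)
    return bs


def _renormalize(bs: BasisSet) -> None:
    from .integrals import overlap_matrix

    s = overlap_matrix(bs)
    scale = 1.0 / np.sqrt(np.diag(s))
    bs.coefs *= scale[:, None]
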