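"""Programmatic test inputs: toy geometries and synthetic orbital tables.

Everything here is constructed in code — no data files.  The geometries are
textbook constructions from standard bond parameters, chosen to span the
correlation regimes the pipeline must handle: H2 stretching (smooth
single-to-multireference crossover), linear H4 (polyradical), twisted
ethylene (strongly multireference closed shell) and trimethylamine (an
ordinary single-reference organic molecule).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .backend.molecule import Molecule


def make_h2(r: float = 0.74, label: str = "h2") -> Molecule:
    if r <= 0:
        raise ValueError("bond length must be positive")
    return Molecule(["H", "H"], [[0.0, 0.0, 0.0], [0.0, 0.0, r]], label=label)


def make_h_atom(label: str = "h") -> Molecule:
    return Molecule(["H"], [[0.0, 0.0, 0.0]], multiplicity=2, label=label)


def make_h4_linear(r: float = 1.0, label: str = "h4") -> Molecule:
    if r <= 0:
        raise ValueError("spacing must be positive")
    coords = [[0.0, 0.0, i * r] for i in range(4)]
    return Molecule(["H"] * 4, coords, label=label)


def make_lih(r: float = 1.595, label: str = "lih") -> Molecule:
    if r <= 0:
        raise ValueError("bond length must be positive")
    return Molecule(["Li", "H"], [[0.0, 0.0, 0.0], [0.0, 0.0, r]], label=label)


def make_ethylene(torsion: float = 0.0, label: str = "ethylene") -> Molecule:
    """Ethylene with the H2C–CH2 dihedral twisted by ``torsion`` degrees.

    90° is the diradicaloid transition-structure analog: the π bond is
    broken while the molecule stays closed shell.
    """
    rcc, rch, theta_deg = 1.339, 1.087, 121.4
    alpha = np.deg2rad(180.0 - theta_deg)  # C–H angle from the +z axis
    tors = np.deg2rad(torsion)
    top, bot = rcc / 2.0, -rcc / 2.0
    coords = [[0.0, 0.0, top], [0.0, 0.0, bot]]
    elements = ["C", "C"]
    for phi in (0.0, np.pi):
        coords.append(
            [
                rch * np.sin(alpha) * np.cos(phi),
                rch * np.sin(alpha) * np.sin(phi),
                top + rch * np.cos(alpha),
            ]
        )
        elements.append("H")
    for phi in (tors, tors + np.pi):
        coords.append(
            [
                rch * np.sin(alpha) * np.cos(phi),
                rch * np.sin(alpha) * np.sin(phi),
                bot - rch * np.cos(alpha),
            ]
        )
        elements.append("H")
    return Molecule(elements, coords, label=label)


def make_trimethylamine(label: str = "trimethylamine") -> Molecule:
    """N(CH3)3 from standard bond parameters (pyramidal C3v skeleton)."""
    rnc, rch = 1.451, 1.09
    cnc = np.deg2rad(110.9)
    # three N–C bonds at equal polar angle below the xy plane
    cos_t2 = (np.cos(cnc) + 0.5) / 1.5
    theta = np.arccos(-np.sqrt(cos_t2))  # point away from the lone pair (+z)
    elements = ["N"]
    coords = [[0.0, 0.0, 0.0]]
    tet = np.deg2rad(109.47)
    for k in range(3):
        phi = 2.0 * np.pi * k / 3.0
        u = np.array(
            [np.sin(theta) * np.cos(phi), np.sin(theta) * np.sin(phi), np.cos(theta)]
        )
        c_pos = rnc * u
        elements.append("C")
        coords.append(c_pos.tolist())
        # local frame at the carbon: C–N bond along −u
        ref = np.array([0.0, 0.0, 1.0])
        w1 = ref - (ref @ u) * u
        w1 /= np.linalg.norm(w1)
        w2 = np.cross(u, w1)
        for m in range(3):
            psi = 2.0 * np.pi * m / 3.0 + np.pi / 3.0  # staggered
            d = np.cos(tet) * (-u) + np.sin(tet) * (
                np.cos(psi) * w1 + np.sin(psi) * w2
            )
            elements.append("H")
            coords.append((c_pos + rch * d).tolist())
    return Molecule(elements, coords, label=label)


def two_h_atoms(separation: float = 100.0, label: str = "2h") -> Molecule:
    """Two H atoms at large separation as a single singlet 'supermolecule'."""
    return Molecule(
        ["H", "H"], [[0.0, 0.0, 0.0], [0.0, 0.0, separation]], label=label
    )


# --------------------------------------------------------------- orbital stubs


@dataclass
class OrbitalTable:
    """ScfResult-shaped stub carrying only what APC selection consumes."""

    occupations: np.ndarray
    fock_diagonal: np.ndarray
    exchange_diagonal: np.ndarray
    converged: bool = True

    @property
    def n_mo(self) -> int:
        return len(self.occupations)


def make_random_orbital_table(
    n_docc: int, n_somo: int, n_virt: int, seed: int
) -> OrbitalTable:
    """Random but reproducible Fock/exchange diagonals with a valid
    occupation pattern: Fock diagonals increase across the
    docc → somo → virtual blocks, exchange diagonals are positive."""
    if min(n_docc, n_somo, n_virt) < 0:
        raise ValueError("orbital counts must be nonnegative")
    rng = np.random.default_rng(seed)
    f_docc = np.sort(rng.uniform(-2.0, -0.3, size=n_docc))
    f_somo = np.sort(rng.uniform(-0.3, -0.05, size=n_somo))
    f_virt = np.sort(rng.uniform(0.05, 2.0, size=n_virt))
    occ = np.concatenate(
        [np.full(n_docc, 2), np.full(n_somo, 1), np.full(n_virt, 0)]
    ).astype(np.int64)
    fock = np.concatenate([f_docc, f_somo, f_virt])
    kdiag = rng.uniform(0.01, 0.8, size=n_docc + n_somo + n_virt)
    return OrbitalTable(occupations=occ, fock_diagonal=fock, exchange_diagonal=kdiag)


def to_xyz(molecule: Molecule, comment: str = "") -> str:
    """Standard XYZ text (Å) for manual CLI runs."""
    lines = [str(len(molecule.elements)), comment or molecule.label]
    for el, (x, y, z) in zip(molecule.elements, molecule.coordinates):
        lines.append(f"{el} {x:.10f} {y:.10f} {z:.10f}")
    return "\n".join(lines) + "\n"
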