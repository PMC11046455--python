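"""Molecular geometry container.

Geometries are inputs to the pipeline (typically externally optimized
structures); nothing in this package moves nuclei.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..units import BOHR_PER_ANGSTROM

_SYMBOLS = [
    "X", "H", "He",
    "Li", "Be", "B", "C", "N", "O", "F", "Ne",
    "Na", "Mg", "Al", "Si", "P", "S", "Cl", "Ar",
]
ATOMIC_NUMBER = {s: z for z, s in enumerate(_SYMBOLS) if z > 0}


@dataclass
class Molecule:
    """A molecular geometry with charge and spin multiplicity.

    Coordinates are Cartesian, in Å. ``multiplicity`` is 2S+1.
    """

    elements: list[str]
    coordinates: np.ndarray  # (natm, 3), Å
    charge: int = 0
    multiplicity: int = 1
    label: str = ""

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float).reshape(-1, 3)
        if len(self.elements) != len(self.coordinates):
            raise ValueError(
                f"{len(self.elements)} element symbols but "
                f"{len(self.coordinates)} coordinate rows"
            )
        if len(self.elements) == 0:
            raise ValueError("empty molecule")
        unknown = [e for e in self.elements if e not in ATOMIC_NUMBER]
        if unknown:
            raise ValueError(f"unknown element symbol(s): {unknown}")
        if self.multiplicity < 1:
            raise ValueError("multiplicity must be a positive integer (2S+1)")
        n_unpaired = self.multiplicity - 1
        if (self.n_electrons - n_unpaired) % 2 != 0 or n_unpaired > self.n_electrons:
            raise ValueError(
                f"multiplicity {self.multiplicity} inconsistent with "
                f"{self.n_electrons} electrons"
            )

    @property
    def atomic_numbers(self) -> np.ndarray:
        return np.array([ATOMIC_NUMBER[e] for e in self.elements], dtype=np.int64)

    @property
    def n_electrons(self) -> int:
        return int(self.atomic_numbers.sum()) - self.charge

    @property
    def coords_bohr(self) -> np.ndarray:
        return self.coordinates * BOHR_PER_ANGSTROM

    def nuclear_repulsion(self) -> float:
        """V_nn in hartree."""
        z = self.atomic_numbers.astype(float)
        r = self.coords_bohr
        e = 0.0
        for i in range(len(z)):
            for j in range(i + 1, len(z)):
                e += z[i] * z[j] / np.linalg.norm(r[i] - r[j])
        return e

    def element_multiset(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for e in self.elements:
            out[e] = out.get(e, 0) + 1
        return out
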