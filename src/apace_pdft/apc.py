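"""Approximate-pair-coefficient (APC) active-space selection.

Orbitals of the converged mean field are ranked by an estimate of how
strongly they correlate, built only from the diagonal elements of the Fock
and exchange matrices.  For every doubly-occupied/virtual pair (i, a) the
pair coefficient is the ground-state mixing coefficient of the 2×2 CI
problem between the reference and the paired double excitation i² → a²,

    A_ia = (Δ_ia − sqrt(Δ_ia² + 4 K_aa²)) / (2 K_aa),   Δ_ia = 2 (F_aa − F_ii),

with the exchange diagonal K_aa standing in for the excitation coupling.
Orbital entropies then condense these interactions: in intermediate
normalization the weight of all excitations touching an orbital p is
p_exc = Σ A² / (1 + Σ A²), and S_p is the two-state entropy
−p ln p − (1−p) ln(1−p) of that weight.

Singly occupied orbitals are never scored: they are forced to the top of
the ranking.  To counter the scheme's bias toward doubly occupied orbitals,
the N highest-entropy virtuals are successively removed from the sums
(entropies recomputed after each removal) and forced to the top as well.
An APC(A,B) active space then takes the A/2 best doubly occupied and
B − A/2 best virtual orbitals (open shells: all SOMOs first).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "PairCoefficientTable",
    "EntropyTable",
    "ActiveSpace",
    "pair_coefficients",
    "orbital_entropies",
    "apply_virtual_removal",
    "select_active_space",
    "select_apc",
    "format_selection_trace",
]


@dataclass
class PairCoefficientTable:
    """Pair coefficients A_ia over (doubly occupied) × (virtual) orbitals."""

    values: np.ndarray  # |docc| x |virt|
    docc_indices: np.ndarray
    virt_indices: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.docc_indices = np.asarray(self.docc_indices, dtype=np.int64)
        self.virt_indices = np.asarray(self.virt_indices, dtype=np.int64)
        if self.values.shape != (len(self.docc_indices), len(self.virt_indices)):
            raise ValueError("pair-coefficient table shape mismatch")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite pair coefficients")


@dataclass
class EntropyTable:
    """Per-orbital entropy scores plus the forced-to-top priority class.

    ``forced_top`` lists orbitals that outrank every scored orbital of their
    occupation class, highest priority first (SOMOs, then removed virtuals
    with later removals first).  Their ``entropy`` entries are left at 0 —
    priority is positional, not a numeric sentinel.
    """

    entropy: np.ndarray  # per MO, >= 0; 0 for unscored orbitals
    forced_top: list[int] = field(default_factory=list)
    n_removed: int = 0
    removed_virtuals: list[int] = field(default_factory=list)  # removal order

    def __post_init__(self) -> None:
        if np.any(self.entropy < 0):
            raise ValueError("entropies must be nonnegative")

    def forced_priority(self, p: int) -> int:
        """0 if not forced; otherwise higher value = higher priority."""
        if p in self.forced_top:
            return len(self.forced_top) - self.forced_top.index(p)
        return 0


@dataclass
class ActiveSpace:
    """(A, B) specification with the selected orbital indices.

    ``provenance`` tags each index as from_docc / from_somo / from_virtual
    according to its mean-field occupation.
    """

    n_electrons: int
    n_orbitals: int
    indices: list[int]
    provenance: list[str]

    def __post_init__(self) -> None:
        if len(self.indices) != self.n_orbitals:
            raise ValueError("|indices| must equal n_orbitals")
        if len(set(self.indices)) != len(self.indices):
            raise ValueError("duplicate orbital indices in active space")
        n_docc = self.provenance.count("from_docc")
        n_somo = self.provenance.count("from_somo")
        if 2 * n_docc + n_somo != self.n_electrons:
            raise ValueError(
                f"provenance implies {2 * n_docc + n_somo} electrons, "
                f"expected {self.n_electrons}"
            )


def _binary_entropy(p: np.ndarray) -> np.ndarray:
    p = np.clip(p, 0.0, 1.0)
    out = np.zeros_like(p)
    mask = (p > 0.0) & (p < 1.0)
    pm = p[mask]
    out[mask] = -pm * np.log(pm) - (1.0 - pm) * np.log(1.0 - pm)
    return out


def pair_coefficients(scf) -> PairCoefficientTable:
    """Approximate pair coefficients from the mean-field diagonals.

    ``scf`` needs ``fock_diagonal``, ``exchange_diagonal`` and
    ``occupations`` (the :class:`~.backend.scf.ScfResult` contract).
    """
    occ = np.asarray(scf.occupations)
    docc = np.where(occ == 2)[0]
    virt = np.where(occ == 0)[0]
    if len(docc) == 0 or len(virt) == 0:
        raise ValueError(
            "pair coefficients need at least one doubly occupied and one "
            f"virtual orbital (got {len(docc)} docc, {len(virt)} virtual)"
        )
    f = np.asarray(scf.fock_diagonal, dtype=float)
    k = np.asarray(scf.exchange_diagonal, dtype=float)
    delta = 2.0 * (f[virt][None, :] - f[docc][:, None])  # Δ_ia
    kaa = np.broadcast_to(k[virt][None, :], delta.shape)
    values = np.zeros_like(delta)
    nonzero = np.abs(kaa) > 1e-14
    values[nonzero] = (
        delta[nonzero] - np.sqrt(delta[nonzero] ** 2 + 4.0 * kaa[nonzero] ** 2)
    ) / (2.0 * kaa[nonzero])
    # K_aa = 0: the coefficient formula is singular; its Δ > 0 limit is 0
    sing = (~nonzero) & (delta <= 0.0)
    if np.any(sing):
        for ii, aa in zip(*np.where(sing)):
            warnings.warn(
                "singular pair-coefficient denominator for pair "
                f"(i={docc[ii]}, a={virt[aa]}): K_aa = 0 with nonpositive gap; "
                "coefficient set to 0",
                stacklevel=2,
            )
    return PairCoefficientTable(values=values, docc_indices=docc, virt_indices=virt)


def _entropies_from_pairs(
    pairs: PairCoefficientTable,
    nmo: int,
    dropped_virtuals: set[int],
    exclude: np.ndarray | None = None,
) -> np.ndarray:
    keep = np.array(
        [j for j, a in enumerate(pairs.virt_indices) if a not in dropped_virtuals],
        dtype=np.int64,
    )
    a2 = pairs.values ** 2
    if exclude is not None:
        a2 = np.where(exclude, 0.0, a2)
    a2 = a2[:, keep] if len(keep) else np.zeros((len(pairs.docc_indices), 0))
    s = np.zeros(nmo)
    sum_i = a2.sum(axis=1)
    s[pairs.docc_indices] = _binary_entropy(sum_i / (1.0 + sum_i))
    if len(keep):
        sum_a = a2.sum(axis=0)
        s[pairs.virt_indices[keep]] = _binary_entropy(sum_a / (1.0 + sum_a))
    return s


def _inverted_pairs(pairs: PairCoefficientTable, scf) -> np.ndarray:
    """Mask of (i, a) pairs whose mean-field gap F_aa − F_ii is not positive.

    Such pairs (degenerate or hole-state mean fields, e.g. homolytic
    dissociation limits) carry divergent pair coefficients that the entropy
    score maps to zero; their members are forced into the active space
    instead of scored.
    """
    f = np.asarray(scf.fock_diagonal, dtype=float)
    delta = f[pairs.virt_indices][None, :] - f[pairs.docc_indices][:, None]
    return delta <= 1e-12


def orbital_entropies(pairs: PairCoefficientTable, scf) -> EntropyTable:
    """Condense pair coefficients into per-orbital entropies.

    SOMOs are placed in the forced-top class (ordered by orbital index);
    their interactions are never computed.
    """
    occ = np.asarray(scf.occupations)
    nmo = len(occ)
    inverted = _inverted_pairs(pairs, scf)
    s = _entropies_from_pairs(pairs, nmo, set(), exclude=inverted)
    somos = [int(p) for p in np.where(occ == 1)[0]]
    forced = somos + _inverted_members(pairs, inverted)
    return EntropyTable(entropy=s, forced_top=forced, n_removed=0)


def _inverted_members(pairs: PairCoefficientTable, inverted: np.ndarray) -> list[int]:
    out: list[int] = []
    for ii, aa in zip(*np.where(inverted)):
        for p in (int(pairs.docc_indices[ii]), int(pairs.virt_indices[aa])):
            if p not in out:
                out.append(p)
    return out


def apply_virtual_removal(
    entropy: EntropyTable, pairs: PairCoefficientTable, scf, n_remove: int = 2
) -> EntropyTable:
    """N-step removal of the highest-entropy virtual from the entropy sums.

    Each removed virtual joins the forced-top class; among removed virtuals
    an earlier removal outranks a later one (the first removal is the
    globally strongest correlator), and all rank below SOMOs.
    """
    if n_remove < 0:
        raise ValueError("n_remove must be >= 0")
    n_virt = len(pairs.virt_indices)
    if n_remove > n_virt:
        raise ValueError(f"cannot remove {n_remove} of {n_virt} virtual orbitals")
    if n_remove == 0:
        return entropy
    occ = np.asarray(scf.occupations)
    nmo = len(occ)
    inverted = _inverted_pairs(pairs, scf)
    prior_forced = [p for p in entropy.forced_top if p not in entropy.removed_virtuals]
    dropped: list[int] = list(entropy.removed_virtuals)
    s = entropy.entropy.copy()
    for _ in range(n_remove):
        candidates = [
            a for a in pairs.virt_indices
            if a not in dropped and a not in prior_forced
        ]
        if not candidates:
            break
        best = max(candidates, key=lambda a: (s[a], -_index_rank(a)))
        dropped.append(int(best))
        s = _entropies_from_pairs(pairs, nmo, set(dropped), exclude=inverted)
    forced = prior_forced + dropped
    return EntropyTable(
        entropy=s,
        forced_top=forced,
        n_removed=entropy.n_removed + n_remove,
        removed_virtuals=dropped,
    )


def _index_rank(p: int) -> int:
    return p


def _ranked(
    indices: np.ndarray, entropy: EntropyTable, fock_diag: np.ndarray, f_homo: float
) -> list[int]:
    """Sort orbital indices best-first: forced class, then entropy, ties by
    smaller |F_pp − F_HOMO|, then by lower index."""
    return sorted(
        (int(p) for p in indices),
        key=lambda p: (
            -entropy.forced_priority(p),
            -entropy.entropy[p],
            abs(fock_diag[p] - f_homo),
            p,
        ),
    )


def select_active_space(
    entropy: EntropyTable, scf, n_elec: int, n_orb: int
) -> ActiveSpace:
    """Fixed-size APC(A, B) selection from the entropy ranking."""
    occ = np.asarray(scf.occupations)
    fock = np.asarray(scf.fock_diagonal, dtype=float)
    docc = np.where(occ == 2)[0]
    somo = np.where(occ == 1)[0]
    virt = np.where(occ == 0)[0]
    n_somo = len(somo)
    if n_orb < 1 or n_elec < 1:
        raise ValueError("active space must contain at least one electron and orbital")
    if n_elec > 2 * n_orb:
        raise ValueError(f"({n_elec},{n_orb}): more than two electrons per orbital")
    if (n_elec - n_somo) % 2 != 0:
        raise ValueError(
            f"A={n_elec} cannot host the {n_somo} singly occupied orbitals "
            "with the remainder paired"
        )
    n_from_docc = (n_elec - n_somo) // 2
    n_from_virt = n_orb - n_somo - n_from_docc
    if n_from_docc < 0:
        raise ValueError(f"A={n_elec} smaller than the {n_somo} SOMOs")
    if n_from_docc > len(docc):
        raise ValueError(
            f"quota needs {n_from_docc} doubly occupied orbitals, "
            f"only {len(docc)} exist"
        )
    if n_from_virt < 0:
        raise ValueError(f"B={n_orb} too small for {n_somo} SOMOs + {n_from_docc} pairs")
    if n_from_virt > len(virt):
        raise ValueError(
            f"quota needs {n_from_virt} virtual orbitals, only {len(virt)} exist"
        )

    occupied = np.concatenate([docc, somo])
    f_homo = float(np.max(fock[occupied])) if len(occupied) else 0.0
    chosen_docc = _ranked(docc, entropy, fock, f_homo)[:n_from_docc]
    chosen_virt = _ranked(virt, entropy, fock, f_homo)[:n_from_virt]
    chosen = sorted(set(chosen_docc) | set(somo.tolist()) | set(chosen_virt))
    prov = []
    for p in chosen:
        if occ[p] == 2:
            prov.append("from_docc")
        elif occ[p] == 1:
            prov.append("from_somo")
        else:
            prov.append("from_virtual")
    return ActiveSpace(
        n_electrons=n_elec, n_orbitals=n_orb, indices=chosen, provenance=prov
    )


def select_apc(scf, n_elec: int, n_orb: int, n_remove: int = 2):
    """Full APC pipeline: pair coefficients → entropies → N-removal → selection.

    Returns (ActiveSpace, EntropyTable, PairCoefficientTable).
    """
    occ = np.asarray(scf.occupations)
    if np.any(occ == 2) and np.any(occ == 0):
        pairs = pair_coefficients(scf)
        ent = orbital_entropies(pairs, scf)
        n_remove_eff = min(n_remove, len(pairs.virt_indices))
        ent = apply_virtual_removal(ent, pairs, scf, n_remove_eff)
    else:
        # no docc/virtual pairs to score (e.g. a lone atom): only the forced
        # SOMO rule and index-order tie-breaking remain
        pairs = PairCoefficientTable(
            values=np.zeros((int(np.sum(occ == 2)), int(np.sum(occ == 0)))),
            docc_indices=np.where(occ == 2)[0],
            virt_indices=np.where(occ == 0)[0],
        )
        ent = EntropyTable(
            entropy=np.zeros(len(occ)),
            forced_top=[int(p) for p in np.where(occ == 1)[0]],
        )
    space = select_active_space(ent, scf, n_elec, n_orb)
    return space, ent, pairs


def format_selection_trace(scf, entropy: EntropyTable, space: ActiveSpace) -> str:
    """Tab-separated audit table: index, occupation, entropy, forced, selected."""
    lines = ["orbital\toccupation\tentropy\tforced\tselected"]
    sel = set(space.indices)
    for p in range(len(scf.occupations)):
        lines.append(
            f"{p}\t{int(scf.occupations[p])}\t{entropy.entropy[p]:.8f}"
            f"\t{int(entropy.forced_priority(p) > 0)}\t{int(p in sel)}"
        )
    return "\n".join(lines) + "\n"
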