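"""Reaction-triple pipeline: mean field → APC → CASSCF → tPBE per state.

A reaction is three all-atom "preassociated" geometries (reactant,
transition state, product) sharing one element multiset, charge and spin.
Each state gets its own APC-selected active space, but all three share the
same (A, B) size — size consistency is enforced, orbital identity is not.
ΔE and the forward/backward barriers are reported per method in kcal/mol
together with the deviations from the single-reference limits.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import apc as apc_mod
from . import diagnostics, pdft
from .backend import build_grid, compute_integrals, run_casscf, run_mean_field
from .backend.grid import DEFAULT_LEVEL
from .backend.molecule import Molecule
from .units import HARTREE_TO_KCAL

logger = logging.getLogger(__name__)

METHODS = ("hf", "casscf", "tpbe", "hf_pbe")


@dataclass
class RunConfig:
    """Resolved run parameters; production defaults are APC(12,12)/cc-pVDZ
    with N = 2 virtual removals."""

    basis: str = "cc-pvdz"
    active_electrons: int = 12
    active_orbitals: int = 12
    n_remove: int = 2
    charge: int = 0
    multiplicity: int = 1
    grid_level: int = DEFAULT_LEVEL
    conv_energy_scf: float = 1e-9
    conv_grad_casscf: float = 1e-6
    reference_table: str | None = None

    def __post_init__(self) -> None:
        if self.active_orbitals < (self.active_electrons + 1) // 2:
            raise ValueError(
                f"B={self.active_orbitals} cannot host A={self.active_electrons} electrons"
            )

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class StateResult:
    label: str
    energies: dict[str, float] = field(default_factory=dict)  # hartree
    mr: diagnostics.MrAssessment | None = None
    active_space: apc_mod.ActiveSpace | None = None
    converged: dict[str, bool] = field(default_factory=dict)
    selection_trace: str = ""
    natural_occupations: list[float] = field(default_factory=list)
    notes: list[str] = field(default_factory=list)
    error: str | None = None

    @property
    def ok(self) -> bool:
        return self.error is None and all(self.converged.values())


@dataclass
class ReactionRecord:
    reactant: StateResult
    ts: StateResult
    product: StateResult
    config: RunConfig
    delta_e: dict[str, float] = field(default_factory=dict)  # kcal/mol
    ea_forward: dict[str, float] = field(default_factory=dict)
    ea_backward: dict[str, float] = field(default_factory=dict)
    srl: list[diagnostics.SrlDeviation] = field(default_factory=list)

    @property
    def states(self) -> tuple[StateResult, StateResult, StateResult]:
        return (self.reactant, self.ts, self.product)


# ------------------------------------------------------------------ pipeline


def run_state(molecule: Molecule, config: RunConfig) -> StateResult:
    """Full per-geometry pipeline; failures flag the state instead of raising."""
    out = StateResult(label=molecule.label or "state")
    try:
        ints = compute_integrals(molecule, config.basis)
        scf = run_mean_field(
            molecule, config.basis, conv_energy=config.conv_energy_scf, integrals=ints
        )
        out.energies["hf"] = scf.total_energy
        out.converged["scf"] = scf.converged
    except Exception as exc:  # noqa: BLE001 - partial reporting is the contract
        out.error = f"mean field failed: {exc}"
        out.converged["scf"] = False
        return out
    try:
        space, entropy, _pairs = apc_mod.select_apc(
            scf,
            config.active_electrons,
            config.active_orbitals,
            n_remove=config.n_remove,
        )
        out.active_space = space
        out.selection_trace = apc_mod.format_selection_trace(scf, entropy, space)
    except Exception as exc:  # noqa: BLE001
        out.error = f"active-space selection failed: {exc}"
        return out
    try:
        cas = run_casscf(scf, space, molecule, conv_grad=config.conv_grad_casscf)
        out.energies["casscf"] = cas.total_energy
        out.converged["casscf"] = cas.converged
        out.natural_occupations = [float(x) for x in cas.natural_occupations]
    except Exception as exc:  # noqa: BLE001
        out.error = f"CASSCF failed: {exc}"
        out.converged["casscf"] = False
        return out
    try:
        out.mr = diagnostics.assess(cas)
    except ValueError as exc:
        # e.g. an all-SOMO active space has no virtual role; energies remain valid
        out.notes.append(f"diagnostics unavailable: {exc}")
    try:
        grid = build_grid(molecule, ints.basis, level=config.grid_level)
        out.energies["tpbe"] = pdft.mcpdft_energy(
            cas, molecule, grid, allow_unconverged=True
        ).total
        out.energies["hf_pbe"] = pdft.hf_pbe_energy(scf, molecule, grid).total
        out.converged["pdft"] = True
    except Exception as exc:  # noqa: BLE001
        out.error = f"MC-PDFT failed: {exc}"
        out.converged["pdft"] = False
    return out


def _check_triple(reactant: Molecule, ts: Molecule, product: Molecule) -> None:
    ref = reactant.element_multiset()
    for other in (ts, product):
        if other.element_multiset() != ref:
            raise ValueError(
                "stoichiometry violation: element multisets differ "
                f"({ref} vs {other.element_multiset()})"
            )
        if (other.charge, other.multiplicity) != (reactant.charge, reactant.multiplicity):
            raise ValueError("charge/multiplicity differ between states")


def run_reaction(
    reactant: Molecule,
    ts: Molecule,
    product: Molecule,
    config: RunConfig,
    reference_energies: pd.DataFrame | None = None,
) -> ReactionRecord:
    """Three state runs with a shared (A, B) size, assembled into ΔE / Ea."""
    _check_triple(reactant, ts, product)
    states = {}
    for role, mol in (("reactant", reactant), ("ts", ts), ("product", product)):
        states[role] = run_state(mol, config)
    rec = ReactionRecord(
        reactant=states["reactant"], ts=states["ts"], product=states["product"],
        config=config,
    )
    if reference_energies is None and config.reference_table:
        reference_energies = import_reference_energies(config.reference_table)
    if reference_energies is not None:
        _attach_references(rec, reference_energies)
    methods = set(rec.reactant.energies) & set(rec.ts.energies) & set(rec.product.energies)
    for m in sorted(methods):
        e_r = rec.reactant.energies[m]
        e_t = rec.ts.energies[m]
        e_p = rec.product.energies[m]
        rec.delta_e[m] = (e_p - e_r) * HARTREE_TO_KCAL
        rec.ea_forward[m] = (e_t - e_r) * HARTREE_TO_KCAL
        rec.ea_backward[m] = (e_t - e_p) * HARTREE_TO_KCAL
    if all(s.mr is not None for s in rec.states):
        rec.srl = diagnostics.srl_deviations(rec)
    return rec


def _attach_references(rec: ReactionRecord, table: pd.DataFrame) -> None:
    for state in rec.states:
        rows = table[table["label"] == state.label]
        for _, row in rows.iterrows():
            method = str(row["method"]).lower()
            if method in METHODS:
                logger.warning(
                    "imported energy for computed method %s ignored", method
                )
                continue
            state.energies[method] = float(row["energy_hartree"])


# ------------------------------------------------------------------ file I/O


def read_xyz(path: str | Path, charge: int = 0, multiplicity: int = 1,
             label: str | None = None) -> Molecule:
    """Standard XYZ: count line, comment line, then `element x y z` in Å."""
    path = Path(path)
    lines = path.read_text().splitlines()
    if not lines:
        raise ValueError(f"{path}: empty file")
    try:
        natoms = int(lines[0].split()[0])
    except (ValueError, IndexError) as exc:
        raise ValueError(f"{path}:1: bad atom count line: {lines[0]!r}") from exc
    comment = lines[1] if len(lines) > 1 else ""
    if "bohr" in comment.lower() or "au" in comment.lower().split():
        raise ValueError(f"{path}:2: only Å coordinates are supported")
    if len(lines) < 2 + natoms:
        raise ValueError(f"{path}: expected {natoms} atom lines, found {len(lines) - 2}")
    elements, coords = [], []
    for i, ln in enumerate(lines[2 : 2 + natoms], start=3):
        parts = ln.split()
        if len(parts) < 4:
            raise ValueError(f"{path}:{i}: malformed atom line: {ln!r}")
        elements.append(parts[0])
        try:
            coords.append([float(x) for x in parts[1:4]])
        except ValueError as exc:
            raise ValueError(f"{path}:{i}: non-numeric coordinate in {ln!r}") from exc
    return Molecule(
        elements, np.array(coords), charge=charge, multiplicity=multiplicity,
        label=label if label is not None else path.stem,
    )


def write_xyz(molecule: Molecule, path: str | Path) -> None:
    from .fixtures import to_xyz

    Path(path).write_text(to_xyz(molecule))


def import_reference_energies(path: str | Path) -> pd.DataFrame:
    """CSV with columns label, method, energy_hartree (extra columns kept)."""
    df = pd.read_csv(path)
    required = {"label", "method", "energy_hartree"}
    if not required.issubset(df.columns):
        raise ValueError(
            f"reference table must have columns {sorted(required)}, "
            f"got {list(df.columns)}"
        )
    return df


def _state_dict(s: StateResult) -> dict:
    return {
        "label": s.label,
        "energies_hartree": s.energies,
        "converged": s.converged,
        "error": s.error,
        "notes": s.notes,
        "m_diagnostic": None if s.mr is None else s.mr.m_value,
        "c0_squared": None if s.mr is None else s.mr.c0_squared,
        "mr_category": None if s.mr is None else s.mr.category,
        "natural_occupations": s.natural_occupations,
        "active_space": None
        if s.active_space is None
        else {
            "n_electrons": s.active_space.n_electrons,
            "n_orbitals": s.active_space.n_orbitals,
            "indices": list(map(int, s.active_space.indices)),
            "provenance": s.active_space.provenance,
        },
        "selection_trace": s.selection_trace,
    }


def record_to_dict(rec: ReactionRecord) -> dict:
    return {
        "config": rec.config.to_dict(),
        "states": {role: _state_dict(getattr(rec, role)) for role in
                   ("reactant", "ts", "product")},
        "delta_e_kcal": rec.delta_e,
        "ea_forward_kcal": rec.ea_forward,
        "ea_backward_kcal": rec.ea_backward,
        "srl_deviations": [
            {
                "quantity": d.quantity,
                "mr_method": d.mr_method,
                "srl_method": d.srl_method,
                "deviation_kcal": d.deviation,
                "abs_deviation_kcal": d.abs_deviation,
                "external": d.external,
            }
            for d in rec.srl
        ],
    }


def write_report(rec: ReactionRecord, path: str | Path) -> None:
    """Full-precision JSON report plus a flat 2-decimal CSV next to it."""
    path = Path(path)
    path.write_text(json.dumps(record_to_dict(rec), indent=2))
    rows = []
    for m in sorted(rec.delta_e):
        rows.append(
            {
                "method": m,
                "delta_e_kcal": round(rec.delta_e[m], 2),
                "ea_forward_kcal": round(rec.ea_forward[m], 2),
                "ea_backward_kcal": round(rec.ea_backward[m], 2),
            }
        )
    pd.DataFrame(rows).to_csv(path.with_suffix(".csv"), index=False)


def load_report(path: str | Path):
    """Reload a JSON report into a lightweight record usable by
    :func:`~.diagnostics.aggregate_mad`."""
    from types import SimpleNamespace

    data = json.loads(Path(path).read_text())
    states = {}
    for role in ("reactant", "ts", "product"):
        sd = data["states"][role]
        mr = None
        if sd["m_diagnostic"] is not None:
            mr = diagnostics.MrAssessment(
                m_value=sd["m_diagnostic"],
                c0_squared=sd["c0_squared"],
                category=sd["mr_category"],
            )
        states[role] = SimpleNamespace(label=sd["label"], mr=mr)
    srl = [
        diagnostics.SrlDeviation(
            quantity=d["quantity"],
            mr_method=d["mr_method"],
            srl_method=d["srl_method"],
            deviation=d["deviation_kcal"],
            external=d["external"],
        )
        for d in data["srl_deviations"]
    ]
    return SimpleNamespace(
        reactant=states["reactant"], ts=states["ts"], product=states["product"],
        delta_e=data["delta_e_kcal"], ea_forward=data["ea_forward_kcal"],
        ea_backward=data["ea_backward_kcal"], srl=srl,
    )
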