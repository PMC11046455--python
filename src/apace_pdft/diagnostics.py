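"""Multireference character diagnostics and single-reference-limit deviations.

The M-diagnostic condenses the natural-orbital occupations of an active
space into a single multiconfigurational-character score,

    M = ½ ( 2 − n_HDOMO + n_LUMO + Σ_j |n_SOMO,j − 1| ),

where n_HDOMO is the occupation of the least-occupied natural orbital whose
reference occupation is 2, n_LUMO that of the most-occupied natural orbital
whose reference occupation is 0, and the sum runs over singly occupied
reference orbitals.  M < 0.05 is minimally multiconfigurational,
0.05 < M < 0.1 moderately so, and M > 0.1 substantially so (boundary values
fall to the lower category).

Single-reference-limit (SRL) deviations compare a multireference method with
its single-determinant counterpart (tPBE ↔ HF-PBE, CASSCF ↔ HF, and
NEVPT2 ↔ MP2 when such energies are imported) on reaction energies and
barriers; their category-stratified mean absolute deviations quantify
active-space inconsistency error.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .backend.casscf import CasResult

logger = logging.getLogger(__name__)

#: fixed MR-method → single-reference-limit pairs that the pipeline computes
SRL_PAIRS: dict[str, str] = {"tpbe": "hf_pbe", "casscf": "hf"}
#: imported-method pairs recognized in external reference tables
IMPORTED_SRL_PAIRS: dict[str, str] = {"nevpt2": "mp2"}

CATEGORIES = ("low", "moderate", "high")
QUANTITIES = ("reaction_energy", "ea_forward", "ea_backward")


@dataclass
class MrAssessment:
    m_value: float
    c0_squared: float
    category: str


@dataclass
class SrlDeviation:
    quantity: str  # reaction_energy | ea_forward | ea_backward
    mr_method: str
    srl_method: str
    deviation: float  # kcal/mol, MR − SRL
    external: bool = False

    @property
    def abs_deviation(self) -> float:
        return abs(self.deviation)


# ------------------------------------------------------------------ M


def m_diagnostic(cas: CasResult) -> float:
    """M-diagnostic from the natural occupations of a CAS wavefunction."""
    occs = np.sort(np.asarray(cas.natural_occupations))[::-1]
    prov = cas.active_space.provenance
    n_docc = prov.count("from_docc")
    n_somo = prov.count("from_somo")
    n_virt = len(prov) - n_docc - n_somo
    if n_virt == 0:
        raise ValueError(
            "M-diagnostic needs at least one virtual-role orbital in the "
            "active space"
        )
    m = 0.0
    if n_docc > 0:
        m += 2.0 - occs[n_docc - 1]  # HDOMO
    m += occs[n_docc + n_somo]  # LUMO
    for j in range(n_docc, n_docc + n_somo):
        m += abs(occs[j] - 1.0)
    return 0.5 * m


def classify(m_value: float) -> str:
    """Threshold M into low / moderate / high multireference character."""
    if m_value < 0.0:
        raise ValueError(f"M-diagnostic cannot be negative (got {m_value})")
    if m_value <= 0.05:
        return "low"
    if m_value <= 0.1:
        return "moderate"
    return "high"


def c0_squared(cas: CasResult) -> float:
    """Weight of the leading CI configuration."""
    if cas.ci_vector is not None:
        return float(np.max(np.asarray(cas.ci_vector) ** 2))
    return float(cas.ci_leading_weight)


def assess(cas: CasResult) -> MrAssessment:
    m = m_diagnostic(cas)
    return MrAssessment(m_value=m, c0_squared=c0_squared(cas), category=classify(m))


# ------------------------------------------------------------------ SRL


def srl_deviations(record) -> list[SrlDeviation]:
    """Deviations of each MR quantity from its single-reference limit.

    ``record`` is a :class:`~.reactions.ReactionRecord`; quantities are read
    from its per-method ΔE / Ea tables (kcal/mol).
    """
    out: list[SrlDeviation] = []
    pairs = dict(SRL_PAIRS)
    for mr, srl in IMPORTED_SRL_PAIRS.items():
        pairs[mr] = srl
    for mr, srl in pairs.items():
        external = mr in IMPORTED_SRL_PAIRS
        for quantity, table in (
            ("reaction_energy", record.delta_e),
            ("ea_forward", record.ea_forward),
            ("ea_backward", record.ea_backward),
        ):
            if mr not in table or srl not in table:
                if mr in table or srl in table:
                    logger.warning(
                        "SRL pair (%s, %s) incomplete for %s; skipped",
                        mr, srl, quantity,
                    )
                continue
            out.append(
                SrlDeviation(
                    quantity=quantity,
                    mr_method=mr,
                    srl_method=srl,
                    deviation=table[mr] - table[srl],
                    external=external,
                )
            )
    return out


def _quantity_category(record, quantity: str) -> str:
    """Stratify a two-state quantity by the larger of its endpoint M values."""
    m_r = record.reactant.mr.m_value
    m_t = record.ts.mr.m_value
    m_p = record.product.mr.m_value
    if quantity == "reaction_energy":
        m = max(m_r, m_p)
    elif quantity == "ea_forward":
        m = max(m_r, m_t)
    elif quantity == "ea_backward":
        m = max(m_t, m_p)
    else:
        raise ValueError(f"unknown quantity {quantity!r}")
    return classify(m)


def aggregate_mad(records: list) -> pd.DataFrame:
    """Category-stratified mean absolute deviations from the SRL.

    One row per (method_pair, quantity, category) actually populated, with
    columns n, mad and max_abs_dev (kcal/mol).  Empty categories are absent.
    """
    rows = []
    for rec in records:
        for dev in rec.srl:
            rows.append(
                {
                    "method_pair": f"{dev.mr_method}-vs-{dev.srl_method}",
                    "quantity": dev.quantity,
                    "category": _quantity_category(rec, dev.quantity),
                    "abs_dev": dev.abs_deviation,
                }
            )
    if not rows:
        return pd.DataFrame(
            columns=["method_pair", "quantity", "category", "n", "mad", "max_abs_dev"]
        )
    df = pd.DataFrame(rows)
    out = (
        df.groupby(["method_pair", "quantity", "category"], sort=True)["abs_dev"]
        .agg(n="count", mad="mean", max_abs_dev="max")
        .reset_index()
    )
    out["n"] = out["n"].astype(int)
    return out
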