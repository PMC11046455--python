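"""MC-PDFT energies with the translated-PBE on-top functional.

The total energy shares its form with KS-DFT,

    E = V_nn + Σ_pq h_pq D_pq + ½ Σ J[ρ] + E_ot[ρ, Π],

but the density ρ and on-top pair density Π come from a multiconfigurational
(CASSCF) wavefunction, and the on-top functional is PBE evaluated on
*effective spin densities* manufactured pointwise from ρ and Π:

    R = Π / (ρ/2)²
    R ≤ 1:  ρ̃↑,↓ = (ρ/2)(1 ± sqrt(1 − R))
    R > 1:  ρ̃↑ = ρ̃↓ = ρ/2

This is the original "t" translation: density gradients are carried along by
the same pointwise factors (∇Π is not used).  Feeding a single determinant
through the identical code path (Π = ρ↑ρ↓) gives the single-reference limit
HF-PBE, i.e. density-corrected PBE; the CASSCF energy itself never enters.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .backend.casscf import CasResult
from .backend.grid import QuadratureGrid
from .backend.molecule import Molecule
from .backend.scf import ScfResult
from .backend.xc import xc_energy_pbe

_RHO_FLOOR = 1e-12
_BATCH = 40000


@dataclass
class OnTopDensities:
    """Grid fields: ρ, ∇ρ, Π, the on-top ratio R and translated spin fields."""

    rho: np.ndarray
    grad_rho: np.ndarray  # (npts, 3)
    pi: np.ndarray
    ratio: np.ndarray | None = None
    rho_eff_up: np.ndarray | None = None
    rho_eff_down: np.ndarray | None = None
    grad_eff_up: np.ndarray | None = None
    grad_eff_down: np.ndarray | None = None


@dataclass
class EnergyBreakdown:
    """Component-resolved total energy, all in hartree."""

    nuclear_repulsion: float
    one_electron: float
    coulomb: float
    on_top: float

    @property
    def total(self) -> float:
        return self.nuclear_repulsion + self.one_electron + self.coulomb + self.on_top

    def to_dict(self) -> dict[str, float]:
        return {
            "nuclear_repulsion": self.nuclear_repulsion,
            "one_electron": self.one_electron,
            "coulomb": self.coulomb,
            "on_top": self.on_top,
            "total": self.total,
        }


# ------------------------------------------------------------------ densities


def densities_on_grid(cas: CasResult, grid: QuadratureGrid) -> OnTopDensities:
    """ρ, ∇ρ and Π of a CAS wavefunction on the grid.

    The inactive (closed-shell) space contributes as a determinant; the
    active contribution to Π is contracted from the active 2-RDM:
    Π = ρ_c²/4 + ρ_c ρ_a / 2 + ½ Σ_tuvw Γ_tuvw φ_t φ_u φ_v φ_w.
    """
    c = cas.optimized_orbitals
    if grid.ao_values.shape[1] != c.shape[0]:
        raise ValueError("grid and orbital dimensions do not match")
    ncore = cas.n_core
    ncas = cas.n_active_orbitals
    occ_mo = c[:, : ncore + ncas]
    npts = grid.n_points
    rho = np.empty(npts)
    grad = np.empty((npts, 3))
    pi = np.empty(npts)
    d1, d2 = cas.rdm1, cas.rdm2
    for start in range(0, npts, _BATCH):
        sl = slice(start, min(start + _BATCH, npts))
        mo = grid.ao_values[sl] @ occ_mo  # (b, ncore+ncas)
        mog = np.einsum("pxa,am->pxm", grid.ao_gradients[sl], occ_mo)
        mo_c, mo_a = mo[:, :ncore], mo[:, ncore:]
        mog_c, mog_a = mog[:, :, :ncore], mog[:, :, ncore:]
        rho_c = 2.0 * np.einsum("pi,pi->p", mo_c, mo_c)
        rho_a = np.einsum("pt,tu,pu->p", mo_a, d1, mo_a, optimize=True)
        rho[sl] = rho_c + rho_a
        grad[sl] = 4.0 * np.einsum("pi,pxi->px", mo_c, mog_c) + 2.0 * np.einsum(
            "pt,tu,pxu->px", mo_a, d1, mog_a, optimize=True
        )
        pair = np.einsum("pt,pu->ptu", mo_a, mo_a)
        pi_act = 0.5 * np.einsum("ptu,tuvw,pvw->p", pair, d2, pair, optimize=True)
        pi[sl] = 0.25 * rho_c**2 + 0.5 * rho_c * rho_a + pi_act
    return OnTopDensities(rho=rho, grad_rho=grad, pi=pi)


def determinant_densities(scf: ScfResult, grid: QuadratureGrid) -> OnTopDensities:
    """ρ, ∇ρ and the determinant on-top density Π = ρ↑ ρ↓ of a mean field."""
    c = scf.orbital_coefficients
    occ = scf.occupations
    ca = c[:, occ >= 1]
    cb = c[:, occ == 2]
    mo_a = grid.ao_values @ ca
    mo_b = grid.ao_values @ cb
    mog_a = np.einsum("pxa,am->pxm", grid.ao_gradients, ca)
    mog_b = np.einsum("pxa,am->pxm", grid.ao_gradients, cb)
    rho_up = np.einsum("pi,pi->p", mo_a, mo_a)
    rho_dn = np.einsum("pi,pi->p", mo_b, mo_b)
    grad = 2.0 * (
        np.einsum("pi,pxi->px", mo_a, mog_a) + np.einsum("pi,pxi->px", mo_b, mog_b)
    )
    return OnTopDensities(rho=rho_up + rho_dn, grad_rho=grad, pi=rho_up * rho_dn)


# ------------------------------------------------------------------ translation


def translate_tpbe(densities: OnTopDensities) -> OnTopDensities:
    """Fill the translated effective spin densities (the "t" scheme)."""
    rho = densities.rho
    pi = densities.pi
    live = rho > _RHO_FLOOR
    ratio = np.zeros_like(rho)
    ratio[live] = pi[live] / (0.5 * rho[live]) ** 2
    root = np.sqrt(np.clip(1.0 - ratio, 0.0, None))  # R > 1 clamps to 0
    up = np.where(live, 0.5 * rho * (1.0 + root), 0.0)
    dn = np.where(live, 0.5 * rho * (1.0 - root), 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        cu = np.where(live, up / np.maximum(rho, _RHO_FLOOR), 0.0)
        cd = np.where(live, dn / np.maximum(rho, _RHO_FLOOR), 0.0)
    densities.ratio = ratio
    densities.rho_eff_up = up
    densities.rho_eff_down = dn
    densities.grad_eff_up = cu[:, None] * densities.grad_rho
    densities.grad_eff_down = cd[:, None] * densities.grad_rho
    return densities


# ------------------------------------------------------------------ energies


def _classical_terms(d_ao: np.ndarray, molecule: Molecule, ints) -> tuple[float, float, float]:
    vnn = molecule.nuclear_repulsion()
    e1 = float(np.sum(ints.hcore * d_ao))
    j = np.einsum("pqrs,rs->pq", ints.eri, d_ao, optimize=True)
    e_coul = 0.5 * float(np.sum(j * d_ao))
    return vnn, e1, e_coul


def _ontop_energy(dens: OnTopDensities, grid: QuadratureGrid) -> float:
    translate_tpbe(dens)
    return xc_energy_pbe(
        dens.rho_eff_up, dens.rho_eff_down, dens.grad_eff_up, dens.grad_eff_down,
        grid.weights,
    )


def mcpdft_energy(
    cas: CasResult,
    molecule: Molecule,
    grid: QuadratureGrid,
    allow_unconverged: bool = False,
) -> EnergyBreakdown:
    """Translated-PBE MC-PDFT energy of a CAS wavefunction."""
    if not cas.converged and not allow_unconverged:
        raise ValueError(
            "CASSCF did not converge; pass allow_unconverged=True to override"
        )
    scf = cas.scf
    if scf is None or scf.integrals is None:
        raise ValueError("CasResult must carry its ScfResult/IntegralSet")
    c = cas.optimized_orbitals
    ncore, ncas_ = cas.n_core, cas.n_active_orbitals
    d_mo = np.zeros((c.shape[1], c.shape[1]))
    for i in range(ncore):
        d_mo[i, i] = 2.0
    d_mo[ncore : ncore + ncas_, ncore : ncore + ncas_] = cas.rdm1
    d_ao = c @ d_mo @ c.T
    vnn, e1, e_coul = _classical_terms(d_ao, molecule, scf.integrals)
    dens = densities_on_grid(cas, grid)
    e_ot = _ontop_energy(dens, grid)
    return EnergyBreakdown(vnn, e1, e_coul, e_ot)


def hf_pbe_energy(
    scf: ScfResult, molecule: Molecule, grid: QuadratureGrid
) -> EnergyBreakdown:
    """Single-reference limit: the same energy expression on the determinant's
    densities (density-corrected PBE)."""
    if not scf.converged:
        raise ValueError("mean field did not converge")
    c = scf.orbital_coefficients
    d_ao = (c * scf.occupations) @ c.T
    vnn, e1, e_coul = _classical_terms(d_ao, molecule, scf.integrals)
    dens = determinant_densities(scf, grid)
    e_ot = _ontop_energy(dens, grid)
    return EnergyBreakdown(vnn, e1, e_coul, e_ot)


def ks_pbe_energy(
    scf: ScfResult, molecule: Molecule, grid: QuadratureGrid
) -> EnergyBreakdown:
    """Non-self-consistent PBE on the determinant's spin densities.

    Independent of the on-top translation machinery — the xc integrand takes
    the determinant's ρ↑, ρ↓ directly.  For a closed shell this must agree
    with :func:`hf_pbe_energy` exactly (the R = 1 translation identity).
    """
    c = scf.orbital_coefficients
    occ = scf.occupations
    d_ao = (c * occ) @ c.T
    vnn, e1, e_coul = _classical_terms(d_ao, molecule, scf.integrals)
    ca = c[:, occ >= 1]
    cb = c[:, occ == 2]
    mo_a = grid.ao_values @ ca
    mo_b = grid.ao_values @ cb
    mog_a = np.einsum("pxa,am->pxm", grid.ao_gradients, ca)
    mog_b = np.einsum("pxa,am->pxm", grid.ao_gradients, cb)
    rho_up = np.einsum("pi,pi->p", mo_a, mo_a)
    rho_dn = np.einsum("pi,pi->p", mo_b, mo_b)
    gup = 2.0 * np.einsum("pi,pxi->px", mo_a, mog_a)
    gdn = 2.0 * np.einsum("pi,pxi->px", mo_b, mog_b)
    e_xc = xc_energy_pbe(rho_up, rho_dn, gup, gdn, grid.weights)
    return EnergyBreakdown(vnn, e1, e_coul, e_xc)
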