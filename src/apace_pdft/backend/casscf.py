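"""CASCI / CASSCF on top of the mean-field solution.

Orbital optimization minimizes the CASCI energy over the non-redundant
orbital-rotation manifold (core–active, core–virtual, active–virtual pairs)
with exact analytic gradients from the generalized Fock matrix; the rotation
is parametrized as U = exp(κ) relative to the starting orbitals and the
chain rule through the matrix exponential is evaluated with its Fréchet
derivative, so a quasi-Newton minimizer can run on the exact surface.

The initial orbitals are exactly the (reordered) mean-field orbitals of the
selected active space — the selection, not the optimizer, decides the
correlation channels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import expm, expm_frechet
from scipy.optimize import minimize

from ..apc import ActiveSpace
from .ci import DeterminantSpace
from .molecule import Molecule
from .scf import ScfResult


class CasConvergenceError(RuntimeError):
    pass


@dataclass
class CasResult:
    """Converged active-space wavefunction and its reduced density matrices.

    ``rdm2`` uses chemist index order: E_2e = ½ Σ Γ_pqrs (pq|rs).
    """

    active_space: ActiveSpace
    total_energy: float
    rdm1: np.ndarray  # active block, spin-summed
    rdm2: np.ndarray  # active block, chemist notation
    natural_occupations: np.ndarray  # descending, in [0, 2]
    ci_leading_weight: float
    optimized_orbitals: np.ndarray  # AO x MO, [core | active | virtual]
    converged: bool
    n_core: int
    grad_norm: float = 0.0
    ci_vector: np.ndarray | None = field(default=None, repr=False)
    scf: ScfResult | None = field(default=None, repr=False)

    @property
    def n_active_orbitals(self) -> int:
        return self.rdm1.shape[0]

    @property
    def n_active_electrons(self) -> int:
        return self.active_space.n_electrons


def _transform_eri(eri_ao: np.ndarray, c: np.ndarray) -> np.ndarray:
    x = np.tensordot(eri_ao, c, axes=([3], [0]))
    x = np.tensordot(x, c, axes=([2], [0]))
    x = np.tensordot(x, c, axes=([1], [0]))
    x = np.tensordot(x, c, axes=([0], [0]))
    return x.transpose(3, 2, 1, 0)


def _core_active_pieces(h_mo, eri_mo, ncore, ncas):
    act = slice(ncore, ncore + ncas)
    f_inact = h_mo.copy()
    if ncore:
        j = np.einsum("pqii->pq", eri_mo[:, :, :ncore, :ncore])
        k = np.einsum("piiq->pq", eri_mo[:, :ncore, :ncore, :])
        f_inact = f_inact + 2.0 * j - k
        e_core = np.trace(h_mo[:ncore, :ncore]) + np.trace(f_inact[:ncore, :ncore])
    else:
        e_core = 0.0
    h_act = f_inact[act, act].copy()
    g_act = eri_mo[act, act, act, act].copy()
    return e_core, h_act, g_act, f_inact


def run_casscf(
    scf: ScfResult,
    active: ActiveSpace,
    molecule: Molecule | None = None,
    conv_grad: float = 1e-6,
    max_iter: int = 300,
    optimize_orbitals: bool = True,
    raise_on_nonconvergence: bool = False,
) -> CasResult:
    """Orbital-optimized CASSCF for the ground state of the molecule's spin."""
    molecule = molecule if molecule is not None else scf.molecule
    ints = scf.integrals
    if ints is None:
        raise ValueError("ScfResult must carry its IntegralSet")
    nmo = scf.orbital_coefficients.shape[1]
    ncas = active.n_orbitals
    nelecas = active.n_electrons
    if nelecas > 2 * ncas:
        raise ValueError(f"cannot place {nelecas} electrons in {ncas} orbitals")

    act_idx = list(active.indices)
    somos = set(scf.somo_indices.tolist())
    if not somos.issubset(act_idx):
        raise ValueError("all singly occupied orbitals must be inside the active space")
    core_idx = [i for i in scf.docc_indices if i not in act_idx]
    virt_idx = [i for i in range(nmo) if i not in act_idx and i not in core_idx]
    ncore = len(core_idx)
    if 2 * ncore + nelecas != scf.n_electrons:
        raise ValueError(
            f"active space ({nelecas},{ncas}) inconsistent with "
            f"{scf.n_electrons} electrons and {ncore} inactive orbitals"
        )
    order = core_idx + act_idx + virt_idx
    c0 = scf.orbital_coefficients[:, order].copy()

    spin_s = 0.5 * (molecule.multiplicity - 1)
    n_alpha = (nelecas + molecule.multiplicity - 1) // 2
    n_beta = nelecas - n_alpha
    space = DeterminantSpace(ncas, n_alpha, n_beta)

    hcore_ao, eri_ao, vnn = ints.hcore, ints.eri, molecule.nuclear_repulsion()
    nvirt = nmo - ncore - ncas
    pairs = (
        [(i, ncore + t) for i in range(ncore) for t in range(ncas)]
        + [(i, ncore + ncas + a) for i in range(ncore) for a in range(nvirt)]
        + [(ncore + t, ncore + ncas + a) for t in range(ncas) for a in range(nvirt)]
    )
    npar = len(pairs)

    state = {}

    def _unpack(x):
        k = np.zeros((nmo, nmo))
        for val, (p, q) in zip(x, pairs):
            k[p, q] = val
            k[q, p] = -val
        return k

    def _energy_and_gradfock(c):
        h_mo = c.T @ hcore_ao @ c
        eri_mo = _transform_eri(eri_ao, c)
        e_core, h_act, g_act, f_inact = _core_active_pieces(h_mo, eri_mo, ncore, ncas)
        e_act, vec = space.ground_state(h_act, g_act, spin_s)
        d1, d2 = space.make_rdm12(vec)
        energy = vnn + e_core + e_act
        # generalized Fock (rows: occupied spaces only)
        act = slice(ncore, ncore + ncas)
        f_act = np.einsum(
            "tu,pqtu->pq", d1, eri_mo[:, :, act, act]
        ) - 0.5 * np.einsum("tu,ptuq->pq", d1, eri_mo[:, act, act, :])
        fgen = np.zeros((nmo, nmo))
        if ncore:
            fgen[:ncore, :] = 2.0 * (f_inact + f_act)[:, :ncore].T
        fgen[act, :] = d1 @ f_inact[:, act].T + np.einsum(
            "tuvw,puvw->tp", d2, eri_mo[:, act, act, act]
        )
        grad_mat = 2.0 * (fgen - fgen.T)
        return energy, grad_mat, vec, d1, d2

    def fun(x):
        k = _unpack(x)
        u = expm(k)
        c = c0 @ u
        energy, grad_mat, vec, d1, d2 = _energy_and_gradfock(c)
        # chain rule through U = exp(κ) in one adjoint Fréchet evaluation:
        # Σ_pq G_pq (Uᵀ L(κ,B))_pq = ⟨L(κᵀ, U G), B⟩ for any direction B
        w = expm_frechet(k.T, u @ grad_mat, compute_expm=False)
        grad = np.array([-0.5 * (w[p, q] - w[q, p]) for (p, q) in pairs])
        state["last"] = (energy, grad_mat, vec, d1, d2, c)
        return energy, grad

    if npar == 0 or not optimize_orbitals:
        energy, grad_mat, vec, d1, d2 = _energy_and_gradfock(c0)
        c_fin = c0
        gnorm = 0.0
        success = True
    else:
        res = minimize(
            fun,
            np.zeros(npar),
            jac=True,
            method="L-BFGS-B",
            options={"maxiter": max_iter, "gtol": conv_grad, "ftol": 1e-13},
        )
        energy, grad_mat, vec, d1, d2, c_fin = state["last"]
        # re-evaluate at the optimizer's solution if it isn't the last call
        k = _unpack(res.x)
        c_fin = c0 @ expm(k)
        energy, grad_mat, vec, d1, d2 = _energy_and_gradfock(c_fin)
        gvec = np.array([grad_mat[p, q] for (p, q) in pairs])
        gnorm = float(np.max(np.abs(gvec))) if npar else 0.0
        success = bool(res.success) and gnorm < 50 * conv_grad
        if raise_on_nonconvergence and not success:
            raise CasConvergenceError(
                f"CASSCF not converged: |g|={gnorm:.2e} after {res.nit} iterations"
            )

    occs = np.linalg.eigvalsh(d1)[::-1].copy()
    occs = np.clip(occs, 0.0, 2.0)
    leading = float(np.max(vec**2))
    return CasResult(
        active_space=active,
        total_energy=float(energy),
        rdm1=d1,
        rdm2=d2,
        natural_occupations=occs,
        ci_leading_weight=leading,
        optimized_orbitals=c_fin,
        converged=success,
        n_core=ncore,
        grad_norm=gnorm,
        ci_vector=vec,
        scf=scf,
    )
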