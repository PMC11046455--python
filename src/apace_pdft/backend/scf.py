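"""Restricted (closed-shell) and restricted-open-shell Hartree–Fock.

The open-shell mean field is ROHF so that every orbital carries an integer
occupation in {0, 1, 2}: the pair-coefficient selection downstream needs a
categorical doubly-occupied / singly-occupied / virtual partition.

Alongside the canonical orbitals, the result carries the diagonal elements of
the Fock matrix F_pp and of the exchange matrix K_pp in the converged MO
basis; these two diagonals are the only electronic-structure input the
active-space selection consumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import eigh

from .basis import BasisSet, build_basis
from .integrals import (
    eri_tensor,
    kinetic_matrix,
    nuclear_attraction_matrix,
    overlap_matrix,
)
from .molecule import Molecule


class ScfConvergenceError(RuntimeError):
    def __init__(self, n_iter: int, energy_change: float, grad_norm: float):
        super().__init__(
            f"SCF failed to converge in {n_iter} iterations "
            f"(last dE={energy_change:.3e}, |[F,P]|={grad_norm:.3e})"
        )
        self.n_iter = n_iter


@dataclass
class IntegralSet:
    """AO integrals shared by all post-mean-field steps."""

    basis: BasisSet
    s: np.ndarray
    t: np.ndarray
    v: np.ndarray
    eri: np.ndarray

    @property
    def hcore(self) -> np.ndarray:
        return self.t + self.v


@dataclass
class ScfResult:
    """Converged mean-field solution in its canonical MO basis."""

    molecule: Molecule
    basis_name: str
    orbital_coefficients: np.ndarray  # AO x MO
    orbital_energies: np.ndarray
    occupations: np.ndarray  # integers in {0,1,2}
    fock_diagonal: np.ndarray  # F_pp, hartree
    exchange_diagonal: np.ndarray  # K_pp, hartree
    total_energy: float
    n_electrons: int
    converged: bool = True
    integrals: IntegralSet | None = field(default=None, repr=False)
    n_iterations: int = 0

    @property
    def docc_indices(self) -> np.ndarray:
        return np.where(self.occupations == 2)[0]

    @property
    def somo_indices(self) -> np.ndarray:
        return np.where(self.occupations == 1)[0]

    @property
    def virt_indices(self) -> np.ndarray:
        return np.where(self.occupations == 0)[0]


def compute_integrals(molecule: Molecule, basis: str) -> IntegralSet:
    bs = build_basis(molecule, basis)
    s = overlap_matrix(bs)
    t = kinetic_matrix(bs)
    v = nuclear_attraction_matrix(bs, molecule.coords_bohr, molecule.atomic_numbers)
    eri = eri_tensor(bs)
    return IntegralSet(basis=bs, s=s, t=t, v=v, eri=eri)


def _fix_phases(c: np.ndarray) -> np.ndarray:
    """Deterministic sign convention: largest-|coefficient| entry positive."""
    idx = np.argmax(np.abs(c), axis=0)
    signs = np.sign(c[idx, np.arange(c.shape[1])])
    signs[signs == 0] = 1.0
    return c * signs


class _Diis:
    def __init__(self, max_vec: int = 8):
        self.errs: list[np.ndarray] = []
        self.focks: list[np.ndarray] = []
        self.max_vec = max_vec

    def update(self, f: np.ndarray, err: np.ndarray) -> np.ndarray:
        self.errs.append(err.ravel().copy())
        self.focks.append(f.copy())
        if len(self.errs) > self.max_vec:
            self.errs.pop(0)
            self.focks.pop(0)
        n = len(self.errs)
        if n < 2:
            return f
        b = -np.ones((n + 1, n + 1))
        b[n, n] = 0.0
        for i in range(n):
            for j in range(n):
                b[i, j] = self.errs[i] @ self.errs[j]
        rhs = np.zeros(n + 1)
        rhs[n] = -1.0
        try:
            coef = np.linalg.solve(b, rhs)[:n]
        except np.linalg.LinAlgError:
            return f
        return sum(c * fk for c, fk in zip(coef, self.focks))


def run_mean_field(
    molecule: Molecule,
    basis: str,
    conv_energy: float = 1e-9,
    conv_grad: float = 1e-7,
    max_iter: int = 200,
    level_shift: float = 0.0,
    integrals: IntegralSet | None = None,
) -> ScfResult:
    """Converge RHF (singlet) or ROHF (higher multiplicity) for the molecule.

    Deterministic: core-Hamiltonian initial guess, fixed DIIS schedule and a
    fixed MO phase convention.  If plain DIIS stalls (typically at orbital
    degeneracies, e.g. stretched bonds), the solve is retried with a fixed
    ladder of virtual level shifts.
    """
    ints = integrals if integrals is not None else compute_integrals(molecule, basis)
    if level_shift != 0.0:
        return _run_mean_field_once(
            molecule, basis, conv_energy, conv_grad, max_iter, level_shift, ints
        )
    last_exc: ScfConvergenceError | None = None
    fallback: ScfResult | None = None
    for shift in (0.0, 0.25, 1.0):
        res = None
        try:
            res = _run_mean_field_once(
                molecule, basis, conv_energy, conv_grad, max_iter, shift, ints
            )
        except ScfConvergenceError as exc:
            last_exc = exc
            continue
        # reject stationary points that violate the aufbau ordering (level
        # shifts can trap hole states); restart from reordered orbitals
        for _ in range(3):
            if _aufbau_ok(res):
                return res
            c_guess = res.orbital_coefficients[:, np.argsort(res.orbital_energies)]
            try:
                res = _run_mean_field_once(
                    molecule, basis, conv_energy, conv_grad, max_iter, shift, ints,
                    c_init=c_guess,
                )
            except ScfConvergenceError as exc:
                last_exc = exc
                res = None
                break
        if res is not None:
            if _aufbau_ok(res):
                return res
            fallback = res if fallback is None else fallback
    if fallback is not None:
        return fallback
    raise last_exc if last_exc is not None else ScfConvergenceError(0, 0.0, 0.0)


def _aufbau_ok(res: "ScfResult", tol: float = 1e-8) -> bool:
    occ_e = res.orbital_energies[res.occupations > 0]
    virt_e = res.orbital_energies[res.occupations == 0]
    if len(occ_e) == 0 or len(virt_e) == 0:
        return True
    return float(np.max(occ_e)) <= float(np.min(virt_e)) + tol


def _run_mean_field_once(
    molecule: Molecule,
    basis: str,
    conv_energy: float,
    conv_grad: float,
    max_iter: int,
    level_shift: float,
    ints: IntegralSet,
    c_init: np.ndarray | None = None,
) -> ScfResult:
    s, hcore, eri = ints.s, ints.hcore, ints.eri
    nao = s.shape[0]
    nelec = molecule.n_electrons
    n_open = molecule.multiplicity - 1
    n_closed = (nelec - n_open) // 2
    if n_closed < 0 or n_closed + n_open > nao:
        raise ValueError(
            f"cannot place {nelec} electrons (multiplicity {molecule.multiplicity}) "
            f"in {nao} orbitals"
        )

    if c_init is None:
        e_orb, c = eigh(hcore, s)
        c = _fix_phases(c)
    else:
        c = c_init
    vnn = molecule.nuclear_repulsion()
    diis = _Diis()
    e_old = 0.0
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        ca = c[:, : n_closed + n_open]
        cb = c[:, :n_closed]
        pa = ca @ ca.T
        pb = cb @ cb.T
        pt = pa + pb
        j = np.einsum("pqrs,rs->pq", eri, pt, optimize=True)
        ka = np.einsum("prqs,rs->pq", eri, pa, optimize=True)
        kb = np.einsum("prqs,rs->pq", eri, pb, optimize=True)
        fa = hcore + j - ka
        fb = hcore + j - kb
        e_elec = 0.5 * (np.sum((hcore + fa) * pa) + np.sum((hcore + fb) * pb))
        e_tot = e_elec + vnn

        if n_open == 0:
            f_eff = 0.5 * (fa + fb)
        else:
            f_eff = _rohf_effective_fock(fa, fb, s, c, n_closed, n_open)
        err = f_eff @ pt @ s - s @ pt @ f_eff
        grad_norm = np.max(np.abs(err))
        de = e_tot - e_old
        if abs(de) < conv_energy and grad_norm < conv_grad and it > 2:
            converged = True
            break
        e_old = e_tot
        f_use = diis.update(f_eff, err)
        if level_shift > 0.0:
            # shift virtual space to damp oscillations near degeneracy
            q_virt = np.linalg.inv(s) - pa
            f_use = f_use + level_shift * (s @ q_virt @ s)
        e_orb, c = eigh(f_use, s)
        c = _fix_phases(c)

    if not converged:
        raise ScfConvergenceError(it, de, grad_norm)

    # canonical orbital energies from the unshifted effective Fock
    f_mo = c.T @ f_eff @ c
    e_orb = np.diag(f_mo).copy()
    # exchange matrix of the total density, MO diagonal
    k_tot = np.einsum("prqs,rs->pq", eri, pa + pb, optimize=True)
    k_diag = np.einsum("up,uv,vp->p", c, k_tot, c, optimize=True)

    occ = np.zeros(nao, dtype=np.int64)
    occ[:n_closed] = 2
    occ[n_closed : n_closed + n_open] = 1
    return ScfResult(
        molecule=molecule,
        basis_name=basis.lower(),
        orbital_coefficients=c,
        orbital_energies=e_orb,
        occupations=occ,
        fock_diagonal=e_orb.copy(),
        exchange_diagonal=k_diag,
        total_energy=float(e_tot),
        n_electrons=nelec,
        converged=True,
        integrals=ints,
        n_iterations=it,
    )


def _rohf_effective_fock(
    fa: np.ndarray,
    fb: np.ndarray,
    s: np.ndarray,
    c: np.ndarray,
    n_closed: int,
    n_open: int,
) -> np.ndarray:
    """Roothaan single-matrix effective Fock in the AO basis.

    Block couplings (closed/open/virtual): cc, oo, vv and cv use the average
    (fa+fb)/2; the closed-open block uses fb and the open-virtual block fa.
    """
    favg = 0.5 * (fa + fb)
    q_c = c[:, :n_closed] @ c[:, :n_closed].T
    q_o = c[:, n_closed : n_closed + n_open] @ c[:, n_closed : n_closed + n_open].T
    q_v = np.linalg.inv(s) - q_c - q_o
    inner = (
        q_c @ favg @ q_c
        + q_o @ favg @ q_o
        + q_v @ favg @ q_v
        + q_c @ fb @ q_o
        + q_o @ fb @ q_c
        + q_c @ favg @ q_v
        + q_v @ favg @ q_c
        + q_o @ fa @ q_v
        + q_v @ fa @ q_o
    )
    f_eff = s @ inner @ s
    return 0.5 * (f_eff + f_eff.T)
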