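"""Determinant-based full CI within an active space.

Determinants are (alpha-string, beta-string) pairs of occupation bitmasks
over the active orbitals.  The Hamiltonian is assembled from sparse
spin-summed excitation operators E_pq; spin purity of the requested state is
enforced by diagonalizing H + λ(S² − S(S+1)) with a positive level shift λ,
which pushes higher-spin roots out of the way without biasing the energy
(H and S² commute in a full CI space).
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import eigsh


def _strings(norb: int, nelec: int) -> list[int]:
    out = []
    for occ in combinations(range(norb), nelec):
        bits = 0
        for o in occ:
            bits |= 1 << o
        out.append(bits)
    return out


def _popcount_below(bits: int, idx: int) -> int:
    return bin(bits & ((1 << idx) - 1)).count("1")


def _single_excitations(strings: list[int], norb: int):
    """For each (p, q): list of (bra_index, ket_index, sign) for a†_p a_q."""
    index = {s: i for i, s in enumerate(strings)}
    table: dict[tuple[int, int], list[tuple[int, int, float]]] = {}
    for p in range(norb):
        for q in range(norb):
            entries = []
            for ik, ket in enumerate(strings):
                if not (ket >> q) & 1:
                    continue
                mid = ket & ~(1 << q)
                sign = (-1.0) ** _popcount_below(ket, q)
                if (mid >> p) & 1:
                    continue
                new = mid | (1 << p)
                sign *= (-1.0) ** _popcount_below(mid, p)
                entries.append((index[new], ik, sign))
            table[(p, q)] = entries
    return table


class DeterminantSpace:
    """FCI space for (n_alpha, n_beta) electrons in norb orbitals."""

    def __init__(self, norb: int, n_alpha: int, n_beta: int):
        self.norb = norb
        self.n_alpha = n_alpha
        self.n_beta = n_beta
        self.astrings = _strings(norb, n_alpha)
        self.bstrings = _strings(norb, n_beta)
        self.na = len(self.astrings)
        self.nb = len(self.bstrings)
        self.ndet = self.na * self.nb
        exc_a = _single_excitations(self.astrings, norb)
        exc_b = _single_excitations(self.bstrings, norb)
        ia, ib = sp.identity(self.na), sp.identity(self.nb)
        self._epq: list[list[sp.csr_matrix]] = []
        for p in range(norb):
            row = []
            for q in range(norb):
                ma = _to_sparse(exc_a[(p, q)], self.na)
                mb = _to_sparse(exc_b[(p, q)], self.nb)
                row.append((sp.kron(ma, ib) + sp.kron(ia, mb)).tocsr())
            self._epq.append(row)
        # dense operator stack for small spaces: Hamiltonian assembly per
        # orbital-optimization step is matmul-bound, not memory-bound
        self._dense = self.ndet <= 600
        if self._dense:
            self._epq_dense = np.stack(
                [self._epq[p][q].toarray() for p in range(norb) for q in range(norb)]
            ).reshape(norb, norb, self.ndet, self.ndet)
        self._s2_cache = None

    def epq(self, p: int, q: int) -> sp.csr_matrix:
        """Spin-summed excitation operator a†_pα a_qα + a†_pβ a_qβ."""
        return self._epq[p][q]

    # ------------------------------------------------------------- operators

    def hamiltonian(self, h1: np.ndarray, g2: np.ndarray) -> sp.csr_matrix:
        """H from active-space h1[p,q] and chemist-notation g2[p,q,r,s]."""
        n = self.norb
        h_eff = h1 - 0.5 * np.einsum("pqqs->ps", g2)
        if self._dense:
            e = self._epq_dense
            h = np.einsum("pq,pqij->ij", h_eff, e, optimize=True)
            c = np.tensordot(g2, e, axes=([2, 3], [0, 1]))  # (p,q,ndet,ndet)
            h += 0.5 * np.einsum("pqij,pqjk->ik", e, c, optimize=True)
            return h
        ham = sp.csr_matrix((self.ndet, self.ndet))
        for p in range(n):
            for q in range(n):
                if abs(h_eff[p, q]) > 1e-16:
                    ham = ham + h_eff[p, q] * self._epq[p][q]
        for p in range(n):
            for q in range(n):
                cpq = sp.csr_matrix((self.ndet, self.ndet))
                for r in range(n):
                    for s in range(n):
                        if abs(g2[p, q, r, s]) > 1e-16:
                            cpq = cpq + g2[p, q, r, s] * self._epq[r][s]
                if cpq.nnz:
                    ham = ham + 0.5 * (self._epq[p][q] @ cpq)
        return ham.tocsr()

    def s2_matrix(self) -> sp.csr_matrix:
        """Total-spin operator S² restricted to this fixed-Sz sector,
        S² = S₋S₊ + Sz(Sz+1); S₊ maps into the (nα+1, nβ−1) sector, so it is
        assembled as a rectangular operator and contracted as S₊†S₊."""
        if self._s2_cache is not None:
            return self._s2_cache
        self._s2_cache = self._build_s2()
        return self._s2_cache

    def _build_s2(self) -> sp.csr_matrix:
        sz = 0.5 * (self.n_alpha - self.n_beta)
        szterm = (sz * (sz + 1)) * sp.identity(self.ndet)
        if self.n_beta == 0 or self.n_alpha == self.norb:
            return szterm.tocsr()
        astr_up = _strings(self.norb, self.n_alpha + 1)
        bstr_dn = _strings(self.norb, self.n_beta - 1)
        idx_a = {s: i for i, s in enumerate(astr_up)}
        idx_b = {s: i for i, s in enumerate(bstr_dn)}
        nb_up = len(bstr_dn)
        # S+ = Σ_p a†_pα a_pβ ; the (−1)^{nα} factor from moving a_pβ past the
        # alpha block is uniform over all terms and cancels in S₋S₊.
        rows, cols, vals = [], [], []
        for ia, astr in enumerate(self.astrings):
            for ib, bstr in enumerate(self.bstrings):
                ket = ia * self.nb + ib
                for p in range(self.norb):
                    if (bstr >> p) & 1 and not (astr >> p) & 1:
                        nb_ = bstr & ~(1 << p)
                        na_ = astr | (1 << p)
                        sgn = (-1.0) ** (
                            _popcount_below(bstr, p) + _popcount_below(astr, p)
                        )
                        bra = idx_a[na_] * nb_up + idx_b[nb_]
                        rows.append(bra)
                        cols.append(ket)
                        vals.append(sgn)
        splus = sp.csr_matrix(
            (vals, (rows, cols)), shape=(len(astr_up) * nb_up, self.ndet)
        )
        return (splus.T @ splus + szterm).tocsr()

    # ------------------------------------------------------------- solve

    def ground_state(
        self, h1: np.ndarray, g2: np.ndarray, spin_s: float, spin_shift: float = 0.5
    ) -> tuple[float, np.ndarray]:
        """Lowest eigenstate with total spin ``spin_s`` at this Sz."""
        ham = self.hamiltonian(h1, g2)
        shift_op = spin_shift * (
            self.s2_matrix() - spin_s * (spin_s + 1) * sp.identity(self.ndet)
        )
        if self._dense:
            pen = ham + shift_op.toarray()
            w, v = np.linalg.eigh(pen)
            vec = v[:, 0]
        else:
            pen = ham + shift_op
            w, v = eigsh(pen, k=1, which="SA", tol=0, maxiter=5000,
                         v0=_det_guess(ham, self.ndet))
            vec = v[:, 0]
        # deterministic phase
        imax = int(np.argmax(np.abs(vec)))
        if vec[imax] < 0:
            vec = -vec
        energy = float(vec @ (ham @ vec))
        return energy, vec

    # ------------------------------------------------------------- densities

    def make_rdm12(self, vec: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Spin-summed 1-RDM D_pq = ⟨E_pq⟩ and chemist 2-RDM Γ_pqrs with
        E_2e = ½ Σ Γ_pqrs (pq|rs)."""
        n = self.norb
        if self._dense:
            x = np.tensordot(self._epq_dense, vec, axes=([3], [0]))
        else:
            x = np.empty((n, n, self.ndet))
            for p in range(n):
                for q in range(n):
                    x[p, q] = self._epq[p][q] @ vec
        d1 = np.einsum("pqi,i->pq", x, vec)
        gamma = np.einsum("qpi,rsi->pqrs", x, x)
        for q in range(n):
            gamma[:, q, q, :] -= d1
        return d1, gamma


def _to_sparse(entries, n):
    if not entries:
        return sp.csr_matrix((n, n))
    rows = [e[0] for e in entries]
    cols = [e[1] for e in entries]
    vals = [e[2] for e in entries]
    return sp.csr_matrix((vals, (rows, cols)), shape=(n, n))


def _det_guess(ham: sp.csr_matrix, ndet: int) -> np.ndarray:
    i0 = int(np.argmin(ham.diagonal()))
    v0 = np.zeros(ndet)
    v0[i0] = 1.0
    return v0
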