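"""Spin-polarized PBE exchange-correlation energy on a quadrature grid.

Exchange uses the PBE enhancement factor over LDA with the exact spin-scaling
relation E_x[n↑,n↓] = (E_x[2n↑] + E_x[2n↓])/2.  Correlation is the
Perdew–Wang 92 local part plus the PBE gradient correction H(rs, ζ, t).
Pure functions of the densities and gradients handed in — no self-consistency.
"""

from __future__ import annotations

import numpy as np

_KAPPA = 0.804
_MU = 0.2195149727645171
_BETA = 0.06672455060314922
_GAMMA = 0.031090690869654895  # (1 - ln 2) / π²
_FZ20 = 1.709920934161365  # f''(0)

_DENSITY_FLOOR = 1e-12


def _pw92_g(rs: np.ndarray, a: float, a1: float, b1: float, b2: float,
            b3: float, b4: float) -> np.ndarray:
    q0 = -2.0 * a * (1.0 + a1 * rs)
    sq = np.sqrt(rs)
    q1 = 2.0 * a * (b1 * sq + b2 * rs + b3 * rs * sq + b4 * rs * rs)
    return q0 * np.log1p(1.0 / q1)


def _eps_c_pw92(rs: np.ndarray, zeta: np.ndarray) -> np.ndarray:
    ec0 = _pw92_g(rs, 0.031091, 0.21370, 7.5957, 3.5876, 1.6382, 0.49294)
    ec1 = _pw92_g(rs, 0.015545, 0.20548, 14.1189, 6.1977, 3.3662, 0.62517)
    mac = _pw92_g(rs, 0.016887, 0.11125, 10.357, 3.6231, 0.88026, 0.49671)
    z4 = zeta**4
    fz = ((1.0 + zeta) ** (4.0 / 3.0) + (1.0 - zeta) ** (4.0 / 3.0) - 2.0) / (
        2.0 ** (4.0 / 3.0) - 2.0
    )
    return ec0 - mac * fz / _FZ20 * (1.0 - z4) + (ec1 - ec0) * fz * z4


def _exchange_density(n: np.ndarray, gnorm: np.ndarray) -> np.ndarray:
    """PBE exchange energy density (per volume) of an unpolarized gas at
    density n with |∇n| = gnorm."""
    ex_lda = -0.75 * (3.0 / np.pi) ** (1.0 / 3.0) * n ** (4.0 / 3.0)
    kf = (3.0 * np.pi**2 * n) ** (1.0 / 3.0)
    s = gnorm / (2.0 * kf * n)
    fx = 1.0 + _KAPPA - _KAPPA / (1.0 + _MU * s**2 / _KAPPA)
    return ex_lda * fx


def pbe_energy_density(
    rho_up: np.ndarray,
    rho_dn: np.ndarray,
    grad_up: np.ndarray,
    grad_dn: np.ndarray,
) -> np.ndarray:
    """Pointwise PBE xc energy per volume; gradients are (npts, 3) vectors."""
    rho_up = np.asarray(rho_up, float)
    rho_dn = np.asarray(rho_dn, float)
    if np.any(rho_up < -1e-10) or np.any(rho_dn < -1e-10):
        raise ValueError("negative spin density passed to the PBE functional")
    rho_up = np.clip(rho_up, 0.0, None)
    rho_dn = np.clip(rho_dn, 0.0, None)
    n = rho_up + rho_dn
    out = np.zeros_like(n)
    live = n > _DENSITY_FLOOR
    if not np.any(live):
        return out
    nu, nd = rho_up[live], rho_dn[live]
    n_ = n[live]
    gu = np.linalg.norm(np.asarray(grad_up, float)[live], axis=1)
    gd = np.linalg.norm(np.asarray(grad_dn, float)[live], axis=1)
    gt = np.linalg.norm(
        np.asarray(grad_up, float)[live] + np.asarray(grad_dn, float)[live], axis=1
    )

    # exchange via spin scaling; empty spin channels contribute zero
    ex = np.zeros_like(n_)
    for nspin, gspin in ((nu, gu), (nd, gd)):
        m = nspin > _DENSITY_FLOOR
        if np.any(m):
            contrib = 0.5 * _exchange_density(2.0 * nspin[m], 2.0 * gspin[m])
            tmp = np.zeros_like(n_)
            tmp[m] = contrib
            ex = ex + tmp

    # correlation
    rs = (3.0 / (4.0 * np.pi * n_)) ** (1.0 / 3.0)
    zeta = np.clip((nu - nd) / n_, -1.0, 1.0)
    eps_c = _eps_c_pw92(rs, zeta)
    phi = 0.5 * ((1.0 + zeta) ** (2.0 / 3.0) + (1.0 - zeta) ** (2.0 / 3.0))
    kf = (3.0 * np.pi**2 * n_) ** (1.0 / 3.0)
    ks = np.sqrt(4.0 * kf / np.pi)
    t2 = (gt / (2.0 * phi * ks * n_)) ** 2
    expo = np.exp(-eps_c / (_GAMMA * phi**3))
    a = _BETA / _GAMMA / np.maximum(expo - 1.0, 1e-300)
    num = 1.0 + a * t2
    den = 1.0 + a * t2 + a**2 * t2**2
    h = _GAMMA * phi**3 * np.log1p(_BETA / _GAMMA * t2 * num / den)
    out[live] = ex + n_ * (eps_c + h)
    return out


def xc_energy_pbe(
    rho_up: np.ndarray,
    rho_dn: np.ndarray,
    grad_up: np.ndarray,
    grad_dn: np.ndarray,
    weights: np.ndarray,
) -> float:
    """Integrated PBE exchange-correlation energy (hartree) on grid weights."""
    e = pbe_energy_density(rho_up, rho_dn, grad_up, grad_dn)
    return float(np.dot(np.asarray(weights, float), e))
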