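"""Steady interstitial fluid pressure (IFP) and Darcy velocity (IFV).

The interstitium is a porous medium: v_i = -kappa * grad(P_i) with
continuity div(v_i) = phi_B - phi_L, where phi_B is the Starling fluid
exchange from the capillaries and phi_L the lymphatic drainage.  The
elliptic problem

    -div(kappa grad P_i) = a_B (P_eff - P_i) - a_L (P_i - P_L)

is discretized with a conservative five-point finite-volume stencil
(harmonic-mean interface conductivity) and Dirichlet P_i = 0 on the outer
boundary; solid tumors then develop the classic elevated-core /
steep-rim IFP profile.  Lymphatic drainage is clamped at phi_L >= 0 (no
backflow) through a small active-set iteration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import sparse
from scipy.sparse.linalg import spsolve

__all__ = [
    "phi_B",
    "phi_L",
    "solve_interstitial_pressure",
    "face_transmissibilities",
    "face_velocities",
    "darcy_velocity",
]


def phi_B(p_b_local, p_i_local, L_p_sv, sigma_s, pi_b, pi_i):
    """Fluid exchange rate from capillaries to interstitium, 1/s.

    phi_B = L_p (S/V) (P_b - P_i - sigma_s (pi_b - pi_i)); ``L_p_sv`` is the
    product L_p * (S/V) in 1/(Pa·s).
    """
    return np.asarray(L_p_sv, dtype=float) * (
        np.asarray(p_b_local, dtype=float)
        - np.asarray(p_i_local, dtype=float)
        - np.asarray(sigma_s, dtype=float)
        * (np.asarray(pi_b, dtype=float) - np.asarray(pi_i, dtype=float))
    )


def phi_L(p_i_local, lymph_coeff, p_L=0.0):
    """Lymphatic drainage rate, 1/s, clamped at zero (no backflow)."""
    raw = np.asarray(lymph_coeff, dtype=float) * (
        np.asarray(p_i_local, dtype=float) - np.asarray(p_L, dtype=float)
    )
    return np.maximum(raw, 0.0)


def face_transmissibilities(kappa: np.ndarray):
    """Harmonic-mean kappa on interior x- and y-faces.

    Returns ``(kx, ky)`` with shapes (n-1, n) and (n, n-1).
    """
    kx = 2.0 * kappa[:-1, :] * kappa[1:, :] / (kappa[:-1, :] + kappa[1:, :])
    ky = 2.0 * kappa[:, :-1] * kappa[:, 1:] / (kappa[:, :-1] + kappa[:, 1:])
    return kx, ky


def _assemble(kappa, h, a_diag):
    """Five-point FV matrix for -div(kappa grad P) + a_diag P (unit depth)."""
    n = kappa.shape[0]
    N = n * n
    kx, ky = face_transmissibilities(kappa)

    def lid(i, j):
        return i * n + j

    ii, jj = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
    rows, cols, vals = [], [], []
    diag = np.zeros((n, n))

    tx = kx / h**2
    diag[:-1, :] += tx
    diag[1:, :] += tx
    rows += [lid(ii[:-1, :], jj[:-1, :]).ravel(), lid(ii[1:, :], jj[1:, :]).ravel()]
    cols += [lid(ii[1:, :], jj[1:, :]).ravel(), lid(ii[:-1, :], jj[:-1, :]).ravel()]
    vals += [-tx.ravel(), -tx.ravel()]

    ty = ky / h**2
    diag[:, :-1] += ty
    diag[:, 1:] += ty
    rows += [lid(ii[:, :-1], jj[:, :-1]).ravel(), lid(ii[:, 1:], jj[:, 1:]).ravel()]
    cols += [lid(ii[:, 1:], jj[:, 1:]).ravel(), lid(ii[:, :-1], jj[:, :-1]).ravel()]
    vals += [-ty.ravel(), -ty.ravel()]

    # Dirichlet P = 0 on the outer boundary through ghost faces at h/2
    tb = 2.0 / h**2
    diag[0, :] += tb * kappa[0, :]
    diag[-1, :] += tb * kappa[-1, :]
    diag[:, 0] += tb * kappa[:, 0]
    diag[:, -1] += tb * kappa[:, -1]

    diag += a_diag
    rows.append(np.arange(N))
    cols.append(np.arange(N))
    vals.append(diag.ravel())
    return sparse.csr_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(N, N),
    )


def solve_interstitial_pressure(
    kappa: np.ndarray,
    h: float,
    a_B: np.ndarray,
    p_eff: np.ndarray,
    lymph_coeff: np.ndarray | float = 0.0,
    p_L: np.ndarray | float = 0.0,
    max_clamp_iter: int = 5,
) -> np.ndarray:
    """Solve the steady IFP field on the square grid.

    Parameters
    ----------
    kappa : (n, n)
        Darcy conductivity field, m^2/(Pa·s).
    h : float
        Grid spacing, m.
    a_B : (n, n)
        Transvascular coefficient L_p (S/V) per cell, 1/(Pa·s); the fluid
        source is a_B * (p_eff - P_i).
    p_eff : (n, n)
        Effective filtration pressure P_b - sigma_s (pi_b - pi_i), Pa.
    lymph_coeff, p_L :
        Lymphatic coefficient (1/(Pa·s)) and lymph pressure (Pa); drainage
        a_L * (P_i - p_L) is clamped at >= 0 via an active-set iteration.

    Returns
    -------
    (n, n) ndarray of P_i, Pa.
    """
    kappa = np.asarray(kappa, dtype=float)
    n = kappa.shape[0]
    a_B = np.broadcast_to(np.asarray(a_B, dtype=float), (n, n))
    p_eff = np.broadcast_to(np.asarray(p_eff, dtype=float), (n, n))
    a_L = np.broadcast_to(np.asarray(lymph_coeff, dtype=float), (n, n)).copy()
    p_L = np.broadcast_to(np.asarray(p_L, dtype=float), (n, n))

    active = a_L > 0
    for _ in range(max_clamp_iter):
        a_Leff = np.where(active, a_L, 0.0)
        A = _assemble(kappa, h, a_B + a_Leff)
        b = (a_B * p_eff + a_Leff * p_L).ravel()
        p = spsolve(A.tocsc(), b)
        if not np.all(np.isfinite(p)):
            raise RuntimeError("interstitial pressure solve failed (non-finite solution)")
        p = p.reshape(n, n)
        backflow = (a_L > 0) & ~active & (p > p_L)
        wrong = (a_L > 0) & active & (p < p_L)
        if not (backflow.any() or wrong.any()):
            break
        active = (a_L > 0) & (p >= p_L)
    resid = A @ p.ravel() - b
    src = np.linalg.norm(b)
    if src > 0 and np.linalg.norm(resid) > 1e-8 * src:
        raise RuntimeError(
            f"interstitial solver residual {np.linalg.norm(resid) / src:.2e} "
            "exceeds tolerance 1e-8"
        )
    return p


def face_velocities(p: np.ndarray, kappa: np.ndarray, h: float):
    """Darcy velocities on all faces, including Dirichlet-0 boundary faces.

    Returns ``(vx, vy)`` with shapes (n+1, n) and (n, n+1); ``vx[i, j]`` is
    the velocity across the face between cells (i-1, j) and (i, j), positive
    along +x.
    """
    n = p.shape[0]
    kx, ky = face_transmissibilities(kappa)
    vx = np.zeros((n + 1, n))
    vy = np.zeros((n, n + 1))
    vx[1:-1, :] = -kx * (p[1:, :] - p[:-1, :]) / h
    vy[:, 1:-1] = -ky * (p[:, 1:] - p[:, :-1]) / h
    # boundary faces: ghost value 0 at h/2
    vx[0, :] = -kappa[0, :] * (p[0, :] - 0.0) / (h / 2.0)
    vx[-1, :] = -kappa[-1, :] * (0.0 - p[-1, :]) / (h / 2.0)
    vy[:, 0] = -kappa[:, 0] * (p[:, 0] - 0.0) / (h / 2.0)
    vy[:, -1] = -kappa[:, -1] * (0.0 - p[:, -1]) / (h / 2.0)
    return vx, vy


def darcy_velocity(p: np.ndarray, kappa: np.ndarray, h: float) -> np.ndarray:
    """Cell-centered Darcy velocity v_i = -kappa grad(P_i), shape (n, n, 2)."""
    vx, vy = face_velocities(p, kappa, h)
    v = np.empty(p.shape + (2,))
    v[..., 0] = 0.5 * (vx[:-1, :] + vx[1:, :])
    v[..., 1] = 0.5 * (vy[:, :-1] + vy[:, 1:])
    return v
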