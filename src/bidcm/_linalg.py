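"""Closed-form propagators for the piecewise-constant bilinear system.

For a bin with constant Jacobian J (2x2) and constant forcing c (2,), the
state update over a step dt is

    x(t+dt) = E x(t) + f,   E = expm(J dt),   f = (E - I) J^{-1} c.

The 2x2 exponential has a closed form via the half-trace mu and the
discriminant delta^2 = (a-d)^2/4 + bc:

    expm(J dt) = e^{mu dt} [ cosh(delta dt) I + sinh(delta dt)/delta (J - mu I) ]

(valid for real or imaginary delta through complex arithmetic).  Near-
singular J falls back to a truncated series for the forced response.
"""

from __future__ import annotations

import numpy as np

__all__ = ["propagators"]


def _sinhc(z: np.ndarray) -> np.ndarray:
    """sinh(z)/z with the z -> 0 limit of 1."""
    out = np.ones_like(z)
    nz = np.abs(z) > 1e-8
    out[nz] = np.sinh(z[nz]) / z[nz]
    return out


def expm2(J: np.ndarray) -> np.ndarray:
    """Matrix exponential of a stack of 2x2 matrices (..., 2, 2)."""
    J = np.asarray(J, float)
    a = J[..., 0, 0]
    b = J[..., 0, 1]
    c = J[..., 1, 0]
    d = J[..., 1, 1]
    mu = 0.5 * (a + d)
    delta = np.sqrt(((a - d) / 2.0) ** 2 + b * c + 0j)
    ch = np.cosh(delta)
    sh = _sinhc(delta)
    E = np.empty(J.shape, dtype=complex)
    E[..., 0, 0] = ch + sh * (a - mu)
    E[..., 0, 1] = sh * b
    E[..., 1, 0] = sh * c
    E[..., 1, 1] = ch + sh * (d - mu)
    return np.real(E * np.exp(mu)[..., None, None])


def propagators(J: np.ndarray, c: np.ndarray, dt: float
                ) -> tuple[np.ndarray, np.ndarray]:
    """Per-bin propagator E = expm(J dt) and forced response f.

    Parameters
    ----------
    J : (..., 2, 2)
        Bin Jacobians A + sum_j u_j B_j.
    c : (..., 2)
        Bin forcings C u.
    dt : float
        Bin width (s).
    """
    J = np.asarray(J, float)
    c = np.asarray(c, float)
    E = expm2(J * dt)
    det = J[..., 0, 0] * J[..., 1, 1] - J[..., 0, 1] * J[..., 1, 0]
    Jinv = np.empty_like(J)
    safe = np.abs(det) > 1e-10
    det_safe = np.where(safe, det, 1.0)
    Jinv[..., 0, 0] = J[..., 1, 1] / det_safe
    Jinv[..., 0, 1] = -J[..., 0, 1] / det_safe
    Jinv[..., 1, 0] = -J[..., 1, 0] / det_safe
    Jinv[..., 1, 1] = J[..., 0, 0] / det_safe
    eye = np.eye(2)
    f = np.einsum("...ij,...jk,...k->...i", E - eye, Jinv, c)
    if not np.all(safe):
        # series fallback: f = dt (I + J dt/2 + (J dt)^2/6) c
        Jd = J * dt
        series = dt * (eye + 0.5 * Jd + (Jd @ Jd) / 6.0)
        f_series = np.einsum("...ij,...j->...i", series, c)
        f = np.where(safe[..., None], f, f_series)
    return E, f
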