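"""Numba forward-model kernel: neural states + balloon haemodynamics.

The neural update per microtime bin is locally exact (matrix exponential of
the bilinear Jacobian with inputs held constant within the bin, precomputed
per distinct input pattern); the four haemodynamic states per region are
integrated with RK4 at the same step, with the neural drive linearly
interpolated within the bin.  Flow, volume and deoxyhemoglobin are carried
in log-space so positivity is structural; the log-states are clamped to
+/-4 inside the rate evaluation so intermediate RK4 stages cannot produce
unbounded stiff rates during distant parameter probes.
"""

from __future__ import annotations

import numpy as np
from numba import njit

#: status value meaning "trajectory stayed finite"
OK = -1

_CLAMP = 4.0


@njit(cache=True, fastmath=True)
def _hemo_rates(s, lf, lv, lq, z, kappa, gamma, tau, ia, lnE1, invE0):
    """Time derivatives of (s, log f, log v, log q) for one region."""
    lfc = min(max(lf, -_CLAMP), _CLAMP)
    lvc = min(max(lv, -_CLAMP), _CLAMP)
    lqc = min(max(lq, -_CLAMP), _CLAMP)
    f = np.exp(lfc)
    fv = np.exp(ia * lvc)            # outflow v**(1/alpha)
    inv_v = np.exp(-lvc)
    inv_q = np.exp(-lqc)
    ds = z - kappa * s - gamma * (f - 1.0)
    dlf = s / f
    dlv = (f - fv) * inv_v / tau
    extraction = (1.0 - np.exp(lnE1 / f)) * invE0
    dlq = (f * extraction * inv_q - fv * inv_v) / tau
    return ds, dlf, dlv, dlq


@njit(cache=True, fastmath=True)
def forward_batch(E, Fc, pat, kappa, tau, eps, gamma, alpha, E0,
                  V0, k1, k2, k3, dt, spp, out):
    """Simulate BOLD for a batch of parameter sets sharing one input train.

    Parameters
    ----------
    E, Fc : (P, K, 2, 2), (P, K, 2)
        Per-bin neural propagators and forced responses for each of the K
        distinct input patterns, per parameter set.
    pat : (n_bins,) int64
        Pattern index of each microtime bin.
    kappa, tau, eps : (P, 2)
        Haemodynamic signal decay (Hz), transit time (s) and neuronal
        efficacy per region.
    gamma, alpha, E0, V0, k1, k2, k3 : float
        Shared haemodynamic constants.
    dt, spp
        Microtime step (s) and bins per scan; scan n is sampled at bin
        n*spp (states at time n*TR).
    out : (P, n_scans, 2)
        Output BOLD, written in place.

    Returns
    -------
    status : (P,) int64
        ``OK`` (-1) or the first microtime bin at which the trajectory left
        the finite range.
    """
    P = E.shape[0]
    n_bins = pat.shape[0]
    n_scans = out.shape[1]
    ia = 1.0 / alpha
    lnE1 = np.log(1.0 - E0)
    invE0 = 1.0 / E0
    status = np.full(P, OK, dtype=np.int64)
    h6 = dt / 6.0
    h2 = 0.5 * dt

    for p in range(P):
        x0 = 0.0
        x1 = 0.0
        s = np.zeros(2)
        lf = np.zeros(2)
        lv = np.zeros(2)
        lq = np.zeros(2)
        bad = False
        for b in range(n_bins):
            if b % spp == 0:
                n = b // spp
                if n < n_scans:
                    for r in range(2):
                        v = np.exp(lv[r])
                        q = np.exp(lq[r])
                        out[p, n, r] = V0 * (k1 * (1.0 - q)
                                             + k2 * (1.0 - q / v)
                                             + k3 * (1.0 - v))
            k = pat[b]
            nx0 = E[p, k, 0, 0] * x0 + E[p, k, 0, 1] * x1 + Fc[p, k, 0]
            nx1 = E[p, k, 1, 0] * x0 + E[p, k, 1, 1] * x1 + Fc[p, k, 1]
            if not (np.isfinite(nx0) and np.isfinite(nx1)) \
                    or abs(nx0) > 1e6 or abs(nx1) > 1e6:
                status[p] = b
                bad = True
                break
            for r in range(2):
                xa = x0 if r == 0 else x1
                xb = nx0 if r == 0 else nx1
                kp = kappa[p, r]
                tp = tau[p, r]
                z0 = eps[p, r] * xa
                zm = eps[p, r] * 0.5 * (xa + xb)
                z1 = eps[p, r] * xb
                a1, b1_, c1, d1 = _hemo_rates(
                    s[r], lf[r], lv[r], lq[r], z0, kp, gamma, tp, ia,
                    lnE1, invE0)
                a2, b2_, c2, d2 = _hemo_rates(
                    s[r] + h2 * a1, lf[r] + h2 * b1_, lv[r] + h2 * c1,
                    lq[r] + h2 * d1, zm, kp, gamma, tp, ia, lnE1, invE0)
                a3, b3_, c3, d3 = _hemo_rates(
                    s[r] + h2 * a2, lf[r] + h2 * b2_, lv[r] + h2 * c2,
                    lq[r] + h2 * d2, zm, kp, gamma, tp, ia, lnE1, invE0)
                a4, b4_, c4, d4 = _hemo_rates(
                    s[r] + dt * a3, lf[r] + dt * b3_, lv[r] + dt * c3,
                    lq[r] + dt * d3, z1, kp, gamma, tp, ia, lnE1, invE0)
                s[r] += h6 * (a1 + 2.0 * a2 + 2.0 * a3 + a4)
                lf[r] += h6 * (b1_ + 2.0 * b2_ + 2.0 * b3_ + b4_)
                lv[r] += h6 * (c1 + 2.0 * c2 + 2.0 * c3 + c4)
                lq[r] += h6 * (d1 + 2.0 * d2 + 2.0 * d3 + d4)
                if lf[r] < -_CLAMP:
                    lf[r] = -_CLAMP
                elif lf[r] > _CLAMP:
                    lf[r] = _CLAMP
                if abs(lv[r]) > 20.0 or abs(lq[r]) > 20.0 \
                        or not np.isfinite(s[r]) or not np.isfinite(lf[r]):
                    status[p] = b
                    bad = True
                    break
            if bad:
                break
            x0 = nx0
            x1 = nx1
    return status
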