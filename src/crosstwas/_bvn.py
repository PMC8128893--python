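"""Vectorized standard bivariate normal probabilities.

Drezner-Wesolowsky quadrature of

    Phi2(h, k; rho) = Phi(h) * Phi(k)
        + (1 / 2*pi) * int_0^rho exp(-(h^2 + k^2 - 2*h*k*r) / (2*(1-r^2)))
                        / sqrt(1 - r^2) dr

evaluated with fixed Gauss-Legendre nodes so that arrays of (h, k, rho)
are handled in one shot.  Accuracy degrades as |rho| -> 1; correlations
are clipped to +-0.9995, which is ample for the Monte-Carlo reference
path that backs every p-value here.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import norm

_NODES, _WEIGHTS = np.polynomial.legendre.leggauss(48)
_RHO_CLIP = 0.9995


def bvn_cdf(h, k, rho):
    """P(X <= h, Y <= k) for standard bivariate normal with correlation rho.

    All three arguments broadcast against each other.
    """
    h = np.asarray(h, dtype=float)
    k = np.asarray(k, dtype=float)
    rho = np.clip(np.asarray(rho, dtype=float), -_RHO_CLIP, _RHO_CLIP)
    h, k, rho = np.broadcast_arrays(h, k, rho)

    # map nodes from [-1, 1] onto [0, rho]
    r = 0.5 * rho[..., None] * (_NODES + 1.0)
    w = 0.5 * rho[..., None] * _WEIGHTS
    hh = h[..., None]
    kk = k[..., None]
    one_m_r2 = 1.0 - r * r
    integrand = np.exp(-(hh * hh + kk * kk - 2.0 * hh * kk * r) / (2.0 * one_m_r2))
    integrand /= np.sqrt(one_m_r2)
    corr_term = (w * integrand).sum(axis=-1) / (2.0 * np.pi)
    out = norm.cdf(h) * norm.cdf(k) + corr_term
    return np.clip(out, 0.0, 1.0)


def both_tails_exceed(t, rho):
    """P(|X| > t, |Y| > t) under correlation rho, for t >= 0.

    By symmetry P(X>t, Y>t) = Phi2(-t, -t; rho) and
    P(X>t, Y<-t) = Phi2(-t, -t; -rho).
    """
    t = np.asarray(t, dtype=float)
    return 2.0 * (bvn_cdf(-t, -t, rho) + bvn_cdf(-t, -t, -rho))
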