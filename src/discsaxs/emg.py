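"""Exponentially modified Gaussian (EMG) peak shape utilities.

The meridional collagen reflection is asymmetric: it is modeled as a Gaussian
(center mu, width sigma) convolved with a one-sided exponential tail of mean
``tau`` toward larger q.  All three parameters carry the units of q (nm^-1).

``emg_shape`` is normalized to unit peak height so an amplitude parameter
multiplies it directly.  The mode and FWHM have no closed form for tau > 0 and
are located numerically; in the tau -> 0 limit they reduce to the Gaussian
mode = mu and FWHM = 2 sqrt(2 ln 2) sigma, which the code switches to below a
small tau/sigma ratio for numerical stability.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.optimize import brentq, minimize_scalar
from scipy.special import erfcx

__all__ = ["GAUSS_FWHM_FACTOR", "emg_pdf", "emg_shape", "emg_mode", "emg_fwhm", "sigma_for_fwhm"]

GAUSS_FWHM_FACTOR = 2.0 * math.sqrt(2.0 * math.log(2.0))

# below this tau/sigma ratio the exponential tail is numerically invisible
_TAU_TINY = 1e-6


def emg_pdf(x: np.ndarray | float, mu: float, sigma: float, tau: float) -> np.ndarray:
    """EMG probability density, numerically stable for all tau/sigma ratios.

    Written with the scaled complementary error function erfcx to avoid the
    overflow of the textbook exp*erfc form when tau << sigma.
    """
    x = np.asarray(x, dtype=float)
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    if tau < 0:
        raise ValueError("tau must be nonnegative")
    if tau <= _TAU_TINY * sigma:
        return np.exp(-0.5 * ((x - mu) / sigma) ** 2) / (sigma * math.sqrt(2 * math.pi))
    scalar = x.ndim == 0
    xv = np.atleast_1d(x)
    lam = 1.0 / tau
    z = (mu + lam * sigma**2 - xv) / (math.sqrt(2.0) * sigma)
    out = np.empty_like(z, dtype=float)
    safe = z > -25.0
    with np.errstate(over="ignore"):
        out[safe] = (
            0.5 * lam * erfcx(z[safe]) * np.exp(-0.5 * ((xv[safe] - mu) / sigma) ** 2)
        )
    # deep exponential tail: erfcx overflows there, but the density reduces to
    # lam * exp(lam*(mu - x) + lam^2 sigma^2 / 2) up to a negligible correction
    if np.any(~safe):
        out[~safe] = lam * np.exp(lam * (mu - xv[~safe]) + 0.5 * (lam * sigma) ** 2)
    return out[0] if scalar else out


def emg_mode(mu: float, sigma: float, tau: float) -> float:
    """Location of the EMG maximum (the reported peak position)."""
    if tau <= _TAU_TINY * sigma:
        return mu
    # the mode sits between the Gaussian center and the tail side
    res = minimize_scalar(
        lambda x: -emg_pdf(x, mu, sigma, tau),
        bounds=(mu - 2.0 * sigma, mu + 3.0 * sigma + 3.0 * tau),
        method="bounded",
        options={"xatol": 1e-12 * max(sigma, tau)},
    )
    return float(res.x)


def emg_fwhm(mu: float, sigma: float, tau: float) -> float:
    """Full width at half maximum of the EMG, located numerically."""
    if tau <= _TAU_TINY * sigma:
        return GAUSS_FWHM_FACTOR * sigma
    mode = emg_mode(mu, sigma, tau)
    half = 0.5 * emg_pdf(mode, mu, sigma, tau)

    def g(x: float) -> float:
        return float(emg_pdf(x, mu, sigma, tau)) - half

    span = sigma + tau
    lo = mode - span
    while g(lo) > 0:
        lo -= span
    hi = mode + span
    while g(hi) > 0:
        hi += span
    left = brentq(g, lo, mode, xtol=1e-14)
    right = brentq(g, mode, hi, xtol=1e-14)
    return right - left


def emg_shape(x: np.ndarray | float, mu: float, sigma: float, tau: float) -> np.ndarray:
    """EMG normalized to unit height at its mode."""
    peak = emg_pdf(emg_mode(mu, sigma, tau), mu, sigma, tau)
    return emg_pdf(x, mu, sigma, tau) / peak


def sigma_for_fwhm(fwhm_target: float, tau: float) -> float:
    """Solve for the Gaussian width giving an EMG the requested FWHM.

    The FWHM is monotone increasing in sigma with infimum ~ tau*ln 2 (the pure
    exponential limit), so targets at or below that are unreachable.
    """
    if fwhm_target <= 0:
        raise ValueError("fwhm_target must be positive")
    floor = tau * math.log(2.0)
    if fwhm_target <= floor * 1.02:
        raise ValueError(
            f"FWHM target {fwhm_target:g} unreachable: exponential tail tau={tau:g} "
            f"alone already gives width ~{floor:g}"
        )
    hi = fwhm_target / GAUSS_FWHM_FACTOR
    lo = max(hi * 1e-3, 1e-12)
    f = lambda s: emg_fwhm(0.0, s, tau) - fwhm_target
    while f(hi) < 0:
        hi *= 2.0
    return float(brentq(f, lo, hi, xtol=1e-14))
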