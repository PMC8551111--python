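"""Bivariate-Gaussian output head and negative log-likelihood.

The network's 5-component output ``h`` parameterizes a bivariate normal
over the next-step displacement via

    mu  = (h[0], h[1])
    sigma = exp(h[2]), exp(h[3])        (strictly positive)
    rho = tanh(h[4])                    (in (-1, 1))

Both the loss value and its analytic gradient with respect to ``h`` are
provided; the gradient is checked against central finite differences in
the test suite.
"""
from __future__ import annotations

import math

import numpy as np

LOG_2PI = math.log(2.0 * math.pi)
# keep exp() finite; gradients are zeroed outside the clamp
_H_SIGMA_CLAMP = 15.0
# keep |rho| strictly below 1 even where tanh rounds to +/-1
_RHO_MAX = 1.0 - 1e-12


def head_to_params(h: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Map raw head output(s) ``(..., 5)`` to (mu, sigma, rho)."""
    h = np.asarray(h, dtype=float)
    mu = h[..., 0:2]
    hs = np.clip(h[..., 2:4], -_H_SIGMA_CLAMP, _H_SIGMA_CLAMP)
    sigma = np.exp(hs)
    rho = np.clip(np.tanh(h[..., 4]), -_RHO_MAX, _RHO_MAX)
    return mu, sigma, rho


def bivariate_nll(
    mu: np.ndarray, sigma: np.ndarray, rho: np.ndarray, y: np.ndarray
) -> np.ndarray:
    """Negative log density of ``y`` under N(mu, sigma, rho), elementwise.

    Broadcasts over leading axes; ``mu``/``sigma``/``y`` have a trailing
    axis of length 2.
    """
    mu = np.asarray(mu, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    rho = np.asarray(rho, dtype=float)
    y = np.asarray(y, dtype=float)
    zx = (y[..., 0] - mu[..., 0]) / sigma[..., 0]
    zy = (y[..., 1] - mu[..., 1]) / sigma[..., 1]
    omr2 = 1.0 - rho**2
    q = (zx**2 - 2.0 * rho * zx * zy + zy**2) / omr2
    return (
        LOG_2PI
        + np.log(sigma[..., 0])
        + np.log(sigma[..., 1])
        + 0.5 * np.log(omr2)
        + 0.5 * q
    )


def nll_from_head(h: np.ndarray, y: np.ndarray) -> np.ndarray:
    """NLL of target displacement(s) ``y`` given raw head output(s)."""
    mu, sigma, rho = head_to_params(h)
    return bivariate_nll(mu, sigma, rho, y)


def nll_and_grad_head(h: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-sample NLL and its gradient w.r.t. the raw head output.

    ``h``: (..., 5); ``y``: (..., 2). Returns (nll (...,), grad (..., 5)).
    """
    h = np.asarray(h, dtype=float)
    y = np.asarray(y, dtype=float)
    mu, sigma, rho = head_to_params(h)
    sx, sy = sigma[..., 0], sigma[..., 1]
    zx = (y[..., 0] - mu[..., 0]) / sx
    zy = (y[..., 1] - mu[..., 1]) / sy
    omr2 = 1.0 - rho**2
    q = zx**2 - 2.0 * rho * zx * zy + zy**2
    nll = LOG_2PI + np.log(sx) + np.log(sy) + 0.5 * np.log(omr2) + 0.5 * q / omr2

    # partials w.r.t. (mu, sigma, rho)
    d_mux = (rho * zy - zx) / (sx * omr2)
    d_muy = (rho * zx - zy) / (sy * omr2)
    d_sx = 1.0 / sx + (rho * zx * zy - zx**2) / (sx * omr2)
    d_sy = 1.0 / sy + (rho * zx * zy - zy**2) / (sy * omr2)
    d_rho = -rho / omr2 + (-zx * zy * omr2 + rho * q) / (omr2**2)

    grad = np.empty_like(h)
    grad[..., 0] = d_mux
    grad[..., 1] = d_muy
    # chain through sigma = exp(h), zero outside the clamp
    in_range = np.abs(h[..., 2:4]) < _H_SIGMA_CLAMP
    grad[..., 2] = np.where(in_range[..., 0], d_sx * sx, 0.0)
    grad[..., 3] = np.where(in_range[..., 1], d_sy * sy, 0.0)
    # chain through rho = tanh(h)
    grad[..., 4] = d_rho * omr2
    return nll, grad
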