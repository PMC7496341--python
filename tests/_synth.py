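"""Synthetic Gaussian channel-output ensembles with known detectability.

Used as the analytic ground truth for observer and learning-curve tests:
for multivariate normal classes N(0, Sigma) and N(dmu, Sigma) the ideal
linear observer is w = Sigma^-1 dmu, its SNR is sqrt(dmu' Sigma^-1 dmu)
and the AUC is Phi(SNR / sqrt(2)).
"""

from __future__ import annotations

import numpy as np
from scipy.special import ndtr, ndtri

from marbench.observer import ChannelOutputs


def random_spd(rng: np.random.Generator, p: int) -> np.ndarray:
    a = rng.normal(size=(p, p))
    return a @ a.T + p * np.eye(p)


def analytic_snr(delta_mu: np.ndarray, sigma: np.ndarray) -> float:
    return float(np.sqrt(delta_mu @ np.linalg.solve(sigma, delta_mu)))


def analytic_auc(delta_mu: np.ndarray, sigma: np.ndarray) -> float:
    return float(ndtr(analytic_snr(delta_mu, sigma) / np.sqrt(2.0)))


def delta_for_auc(auc: float, p: int) -> np.ndarray:
    """Mean-difference along the first axis giving ``auc`` under identity
    covariance."""
    snr = np.sqrt(2.0) * ndtri(auc)
    d = np.zeros(p)
    d[0] = snr
    return d


def gaussian_outputs(
    rng: np.random.Generator,
    n: int,
    delta_mu: np.ndarray,
    sigma: np.ndarray | None = None,
) -> ChannelOutputs:
    p = delta_mu.shape[0]
    if sigma is None:
        v1 = rng.normal(size=(n, p))
        v2 = rng.normal(size=(n, p)) + delta_mu
    else:
        chol = np.linalg.cholesky(sigma)
        v1 = rng.normal(size=(n, p)) @ chol.T
        v2 = rng.normal(size=(n, p)) @ chol.T + delta_mu
    return ChannelOutputs(v1=v1, v2=v2)


def designed_classes(rng: np.random.Generator, p: int = 10, delta_norm: float = 2.0):
    """A well-conditioned designed pair (delta_mu, sigma): mild correlations
    on top of unit variances, mean difference of fixed norm."""
    a = rng.normal(size=(p, p)) / np.sqrt(p)
    sigma = np.eye(p) + 0.3 * (a @ a.T)
    delta = rng.normal(size=p)
    delta *= delta_norm / np.linalg.norm(delta)
    return delta, sigma
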