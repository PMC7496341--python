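"""Channelized Hotelling observer with dense difference-of-Gaussians channels.

The detection task is binary: is the low-contrast disk present at the ROI
center?  Each ROI (a centered ``roi_side x roi_side`` crop, cast row-major
into a q-vector g) is reduced to p = 10 channel outputs v = U^T g, where
the columns of U are radially symmetric DDOG channels.  The Hotelling
template is w = Sigma^-1 dmu with the pooled channel covariance
Sigma = (Sigma_1 + Sigma_2)/2 and the class-mean difference dmu; the test
statistic t = w^T v is treated as binormal, giving

    SNR^2 = |t1_bar - t2_bar|^2 / ((sigma_1^2 + sigma_2^2)/2)
    AUC   = Phi(SNR / sqrt(2)).

A rank-based (Mann-Whitney) empirical AUC is provided as an independent
check of the binormal formula.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import ndtr
from scipy.stats import mannwhitneyu

from .recon import ReconImage

__all__ = [
    "ROI",
    "ChannelBank",
    "ChannelOutputs",
    "CHOTemplate",
    "AUCEstimate",
    "extract_roi",
    "build_ddog_bank",
    "channelize",
    "train_cho",
    "apply_template",
    "snr_from_statistics",
    "auc_binormal",
    "auc_empirical",
]

DEFAULT_N_CHANNELS = 10
DEFAULT_SIGMA0 = 0.005  # cycles/pixel at the full-scale 512 grid
DEFAULT_ALPHA = 1.4
DEFAULT_Q = 1.67


@dataclass(frozen=True)
class ROI:
    """One region of interest as a q-vector of pixel values."""

    g: np.ndarray
    roi_side: int
    provenance: dict | None = None

    def __post_init__(self) -> None:
        if self.roi_side % 2 == 0:
            raise ValueError("roi_side must be odd (center pixel on the signal)")
        if self.g.shape != (self.roi_side**2,):
            raise ValueError("g must have length roi_side**2")


@dataclass(frozen=True)
class ChannelBank:
    """q x p matrix of unit-normalized spatial channel images."""

    U: np.ndarray
    roi_side: int
    sigma0: float
    alpha: float
    Q: float

    @property
    def n_channels(self) -> int:
        return self.U.shape[1]


@dataclass(frozen=True)
class ChannelOutputs:
    """Channel output ensembles: v1 (class 1, signal absent) and v2
    (class 2, signal present), each (n, p)."""

    v1: np.ndarray
    v2: np.ndarray

    def __post_init__(self) -> None:
        if self.v1.ndim != 2 or self.v2.ndim != 2 or self.v1.shape[1] != self.v2.shape[1]:
            raise ValueError("v1 and v2 must be (n, p) with matching p")

    @property
    def n_channels(self) -> int:
        return self.v1.shape[1]


@dataclass(frozen=True)
class CHOTemplate:
    """Trained Hotelling template w = Sigma^-1 dmu."""

    w: np.ndarray
    delta_mu: np.ndarray
    sigma: np.ndarray


@dataclass(frozen=True)
class AUCEstimate:
    snr: float
    auc: float
    n_train: int
    n_test: int
    method: str


def extract_roi(image: ReconImage | np.ndarray, roi_side: int) -> ROI:
    """Centered crop, vectorized row-major."""
    pixels = image.pixels if isinstance(image, ReconImage) else np.asarray(image)
    n = pixels.shape[0]
    if roi_side % 2 == 0:
        raise ValueError("roi_side must be odd")
    if roi_side > n:
        raise ValueError("ROI larger than image")
    c = n // 2
    h = roi_side // 2
    crop = pixels[c - h : c + h + 1, c - h : c + h + 1]
    return ROI(g=np.ascontiguousarray(crop, float).ravel(), roi_side=roi_side)


def build_ddog_bank(
    roi_side: int,
    p: int = DEFAULT_N_CHANNELS,
    sigma0: float = DEFAULT_SIGMA0,
    alpha: float = DEFAULT_ALPHA,
    Q: float = DEFAULT_Q,
) -> ChannelBank:
    """Dense difference-of-Gaussians channel bank on the ROI grid.

    Channel j is defined in radial spatial frequency rho (cycles/pixel) as

        C_j(rho) = exp(-0.5 (rho/(Q sigma_j))^2) - exp(-0.5 (rho/sigma_j)^2),
        sigma_j = sigma0 * alpha**j,  j = 0..p-1,

    which has zero DC response; the spatial channel is its inverse Fourier
    transform on the ROI grid, unit-normalized.
    """
    if p < 1:
        raise ValueError("need at least one channel")
    f = np.fft.fftfreq(roi_side)
    fx, fy = np.meshgrid(f, f)
    rho = np.hypot(fx, fy)
    cols = []
    for j in range(p):
        sj = sigma0 * alpha**j
        resp = np.exp(-0.5 * (rho / (Q * sj)) ** 2) - np.exp(-0.5 * (rho / sj) ** 2)
        spatial = np.fft.fftshift(np.fft.ifft2(resp).real)
        norm = np.linalg.norm(spatial)
        cols.append(spatial.ravel() / norm)
    return ChannelBank(
        U=np.column_stack(cols), roi_side=roi_side, sigma0=sigma0, alpha=alpha, Q=Q
    )


def channelize(rois: np.ndarray, bank: ChannelBank) -> np.ndarray:
    """Channel outputs V = G U for an (n, q) ROI stack (or a single q-vector)."""
    g = np.atleast_2d(np.asarray(rois, float))
    if g.shape[1] != bank.U.shape[0]:
        raise ValueError("ROI dimension does not match channel bank")
    return g @ bank.U


def channel_outputs(
    rois_absent: np.ndarray, rois_present: np.ndarray, bank: ChannelBank
) -> ChannelOutputs:
    """Convenience wrapper building a two-class ChannelOutputs."""
    return ChannelOutputs(
        v1=channelize(rois_absent, bank), v2=channelize(rois_present, bank)
    )


def train_cho(train: ChannelOutputs) -> CHOTemplate:
    """Fit the Hotelling template from training channel outputs.

    dmu is the sample mean difference (class 2 minus class 1); Sigma the
    equal-weight average of the two class sample covariances (n-1
    denominators); w solves Sigma w = dmu.
    """
    v1, v2 = train.v1, train.v2
    p = train.n_channels
    if v1.shape[0] <= p or v2.shape[0] <= p:
        raise ValueError("each class needs more training samples than channels")
    delta_mu = v2.mean(axis=0) - v1.mean(axis=0)
    sigma = 0.5 * (np.cov(v1, rowvar=False) + np.cov(v2, rowvar=False))
    try:
        w = np.linalg.solve(sigma, delta_mu)
    except np.linalg.LinAlgError as err:
        raise np.linalg.LinAlgError(
            "pooled channel covariance is singular; provide more training samples"
        ) from err
    return CHOTemplate(w=w, delta_mu=delta_mu, sigma=sigma)


def apply_template(template: CHOTemplate, v: np.ndarray) -> np.ndarray:
    """Test statistics t = w^T v for an (n, p) stack of channel outputs."""
    return np.atleast_2d(np.asarray(v, float)) @ template.w


def snr_from_statistics(t1: np.ndarray, t2: np.ndarray) -> float:
    """Observer SNR from the two classes of test statistics.

    SNR^2 = |mean(t1) - mean(t2)|^2 / ((var(t1) + var(t2)) / 2).
    """
    t1 = np.asarray(t1, float)
    t2 = np.asarray(t2, float)
    if t1.size < 2 or t2.size < 2:
        raise ValueError("need at least two statistics per class")
    pooled = 0.5 * (t1.var(ddof=1) + t2.var(ddof=1))
    if pooled == 0:
        raise ValueError("zero pooled variance: degenerate test statistics")
    return float(abs(t1.mean() - t2.mean()) / np.sqrt(pooled))


def auc_binormal(snr: float) -> float:
    """AUC = Phi(SNR / sqrt(2)) for binormal test statistics."""
    if snr < 0:
        raise ValueError("snr must be non-negative")
    return float(ndtr(snr / np.sqrt(2.0)))


def auc_empirical(t1: np.ndarray, t2: np.ndarray) -> float:
    """Mann-Whitney AUC: P(t2 > t1), ties counted one half."""
    t1 = np.asarray(t1, float)
    t2 = np.asarray(t2, float)
    if t1.size == 0 or t2.size == 0:
        raise ValueError("both classes must be nonempty")
    u = mannwhitneyu(t2, t1, alternative="two-sided").statistic
    return float(u / (t1.size * t2.size))
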