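"""Synthetic inputs: gaussian/sparse textures, degraded observations, toys.

Stands in for a calibrated natural-image ensemble: zero-mean textures with
a prescribed power spectrum (gaussian coefficients, or heavier-tailed
generalized-gaussian coefficients when a sparse source is needed by the
response-sparsity cost), plus the degradation stage x = As + n and a
two-pixel toy problem for analytical characterization.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .basis import DenseBasis
from .signal_model import (
    BlurModel,
    CodingProblem,
    GridGeometry,
    NoiseLevels,
    SpectralCovariance,
    neural_power_budget,
)

__all__ = ["TextureSpec", "sample_textures", "degrade", "toy2d_problem"]


@dataclass(frozen=True)
class TextureSpec:
    """What to sample: a covariance, a coefficient family, and a seed."""

    covariance: SpectralCovariance
    family: str = "gaussian"  # "gaussian" | "sparse_source"
    sparse_exponent: float = 0.7
    seed: int = 0

    def __post_init__(self):
        if self.family not in ("gaussian", "sparse_source"):
            raise ValueError("family must be 'gaussian' or 'sparse_source'")
        if self.sparse_exponent <= 0:
            raise ValueError("sparse_exponent must be > 0")


def _generalized_gaussian(rng: np.random.Generator, q: float, size) -> np.ndarray:
    """Unit-variance generalized gaussian draws, |z| ~ Gamma(1/q)^(1/q)."""
    from scipy.special import gammaln

    mag = rng.gamma(1.0 / q, 1.0, size) ** (1.0 / q)
    sign = rng.choice([-1.0, 1.0], size)
    scale = np.exp(0.5 * (gammaln(1.0 / q) - gammaln(3.0 / q)))
    return sign * mag * scale


def sample_textures(spec: TextureSpec, n: int) -> np.ndarray:
    """Draw n signal vectors s = E·diag(√λ)·u, u iid unit-variance coefficients.

    Pure function of (spec, n): the same spec yields bit-identical samples.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(spec.seed)
    cov = spec.covariance
    if spec.family == "gaussian":
        u = rng.standard_normal((n, cov.n))
    else:
        u = _generalized_gaussian(rng, spec.sparse_exponent, (n, cov.n))
    e = cov.basis.full()
    return (u * np.sqrt(cov.spectrum)) @ e.T


def degrade(
    samples: np.ndarray,
    blur: BlurModel,
    sensory_variance: float,
    seed: int,
    covariance: SpectralCovariance,
) -> np.ndarray:
    """Observed signals x = A s + n with seeded white gaussian sensory noise."""
    s = np.asarray(samples, dtype=float)
    if s.shape[1] != covariance.n:
        raise ValueError("sample width must match the covariance dimension")
    e = covariance.basis.full()
    x = (s @ e * blur.spectral_gains) @ e.T
    if sensory_variance > 0:
        rng = np.random.default_rng(seed)
        x = x + rng.normal(0.0, np.sqrt(sensory_variance), s.shape)
    return x


def toy2d_problem(
    correlation: float,
    sensory_snr_db: float,
    neural_snr_db: float = 10.0,
    population_size: int = 2,
    neural_variance: float = 1.0,
) -> CodingProblem:
    """Two-pixel signal with covariance [[1, ρ], [ρ, 1]] and no blur.

    Small enough to characterize the optimal code analytically: its
    eigenmodes are the sum/difference pixels with variances 1±ρ.  Under a
    tight budget and strong correlation only the first mode stays active
    and the two receptive fields become proportional (a repetitive code).
    """
    rho = float(correlation)
    if not abs(rho) < 1:
        raise ValueError("|correlation| must be < 1")
    e = np.array([[1.0, 1.0], [1.0, -1.0]]) / np.sqrt(2.0)
    lam = np.array([1.0 + rho, 1.0 - rho])
    cov = SpectralCovariance(
        DenseBasis(e), lam, np.array([0.0, 1.0]), grid=GridGeometry(1, 2)
    )
    blur = BlurModel.identity(2)
    # tr(AΣsAᵀ) = 2 regardless of ρ
    sn2 = 2.0 / (2 * 10.0 ** (sensory_snr_db / 10.0))
    p = neural_power_budget(population_size, neural_variance, neural_snr_db)
    return CodingProblem(cov, blur, NoiseLevels(sn2, neural_variance), population_size, p)
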