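"""Signal statistics, blur, noise levels and capacity accounting.

The generative model: an original signal s (zero mean, covariance
Σs = E Λ Eᵀ) passes through a linear blur A (co-diagonal with E) and picks
up white sensory noise n with variance σn², giving the observed signal
x = A s + n.  A population of M noisy linear units encodes x as
r = W x + δ with white neural noise δ of variance σδ².  SNRs are stated in
dB; the per-neuron capacity of a gaussian channel at a given SNR is
½·log2(1 + SNR).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .basis import DenseBasis, RealFourier2D

__all__ = [
    "GridGeometry",
    "SpectralCovariance",
    "BlurModel",
    "NoiseLevels",
    "CodingProblem",
    "make_powerlaw_spectrum",
    "make_powerlaw_components",
    "empirical_covariance",
    "sensory_noise_for_snr",
    "sensory_snr_db",
    "neural_power_budget",
    "capacity_bits",
]


@dataclass(frozen=True)
class GridGeometry:
    """Integer pixel lattice; N = height × width sensory units."""

    height: int
    width: int

    def __post_init__(self):
        if self.height < 1 or self.width < 1:
            raise ValueError("grid dimensions must be >= 1")

    @property
    def n(self) -> int:
        return self.height * self.width

    def pixel_coords(self) -> np.ndarray:
        """(N, 2) array of (y, x) coordinates in row-major flattening order."""
        yy, xx = np.meshgrid(
            np.arange(self.height), np.arange(self.width), indexing="ij"
        )
        return np.column_stack([yy.ravel(), xx.ravel()])


@dataclass(frozen=True)
class SpectralCovariance:
    """Signal covariance Σs = E diag(spectrum) Eᵀ in its eigenbasis.

    ``basis`` provides the orthonormal eigenvectors (columns = spatial
    modes), ``spectrum`` the per-component variances λ_i ≥ 0, and
    ``frequency_index`` a per-component frequency magnitude (or a plain
    rank index for empirical covariances) used for deterministic
    tie-breaking and for spectral plots.
    """

    basis: object  # RealFourier2D | DenseBasis
    spectrum: np.ndarray
    frequency_index: np.ndarray
    grid: GridGeometry | None = None

    def __post_init__(self):
        lam = np.asarray(self.spectrum, dtype=float)
        fi = np.asarray(self.frequency_index, dtype=float)
        if lam.shape != (self.basis.n,) or fi.shape != (self.basis.n,):
            raise ValueError("spectrum / frequency_index length must equal basis size")
        if np.any(lam < 0):
            raise ValueError("spectrum must be nonnegative")
        object.__setattr__(self, "spectrum", lam)
        object.__setattr__(self, "frequency_index", fi)

    @property
    def n(self) -> int:
        return self.basis.n

    @property
    def trace(self) -> float:
        return float(self.spectrum.sum())

    def matrix(self) -> np.ndarray:
        """Dense Σs (small problems only)."""
        e = self.basis.full()
        return (e * self.spectrum) @ e.T


@dataclass(frozen=True)
class BlurModel:
    """Linear distortion co-diagonal with the signal eigenbasis.

    ``spectral_gains`` holds the modulation transfer function a_i ≥ 0 per
    spectral component; circular convolution in the Fourier basis.
    """

    spectral_gains: np.ndarray

    def __post_init__(self):
        a = np.asarray(self.spectral_gains, dtype=float)
        if a.ndim != 1:
            raise ValueError("spectral_gains must be 1-D")
        if np.any(~np.isfinite(a)) or np.any(a < 0):
            raise ValueError("spectral gains must be finite and nonnegative")
        object.__setattr__(self, "spectral_gains", a)

    @classmethod
    def identity(cls, n: int) -> "BlurModel":
        return cls(np.ones(n))

    @classmethod
    def gaussian(cls, covariance: SpectralCovariance, sigma_pixels: float) -> "BlurModel":
        """Gaussian MTF a(f) = exp(−2π²σ²f²) for a spatial gaussian of std σ px.

        σ = 0 gives the identity (no blur).
        """
        if sigma_pixels < 0:
            raise ValueError("blur sigma must be >= 0")
        f = covariance.frequency_index
        return cls(np.exp(-2.0 * np.pi**2 * sigma_pixels**2 * f**2))


@dataclass(frozen=True)
class NoiseLevels:
    """Sensory noise variance σn² ≥ 0 and neural noise variance σδ² > 0."""

    sensory_variance: float
    neural_variance: float

    def __post_init__(self):
        if self.sensory_variance < 0:
            raise ValueError("sensory_variance must be >= 0")
        if self.neural_variance <= 0:
            raise ValueError("neural_variance must be > 0")


@dataclass(frozen=True)
class CodingProblem:
    """Bundle of signal statistics, blur, noise, population size and power budget."""

    signal: SpectralCovariance
    blur: BlurModel
    noise: NoiseLevels
    population_size: int
    power_budget: float

    def __post_init__(self):
        if self.blur.spectral_gains.shape != (self.signal.n,):
            raise ValueError("blur gains must match signal dimension")
        if self.population_size < 1:
            raise ValueError("population_size must be >= 1")
        if self.power_budget <= 0:
            raise ValueError("power_budget must be > 0")

    @property
    def n(self) -> int:
        return self.signal.n

    @property
    def m(self) -> int:
        return self.population_size

    def observed_spectrum(self) -> np.ndarray:
        """Per-component variance of the observed signal, a_i²λ_i + σn²."""
        a = self.blur.spectral_gains
        return a**2 * self.signal.spectrum + self.noise.sensory_variance

    @classmethod
    def from_snr(
        cls,
        signal: SpectralCovariance,
        blur: BlurModel,
        population_size: int,
        sensory_snr_db: float,
        neural_snr_db: float = 10.0,
        neural_variance: float = 1.0,
    ) -> "CodingProblem":
        """Build a problem from SNRs in dB (power budget P = M σδ² 10^(SNR/10))."""
        sn2 = sensory_noise_for_snr(signal, blur, sensory_snr_db)
        p = neural_power_budget(population_size, neural_variance, neural_snr_db)
        return cls(signal, blur, NoiseLevels(sn2, neural_variance), population_size, p)


def make_powerlaw_spectrum(grid: GridGeometry, exponent: float = 2.0) -> SpectralCovariance:
    """1/f^exponent spectral covariance on the real 2-D Fourier basis.

    The DC component (f = 0) is set to zero variance (zero-mean signal) and
    the spectrum is normalized so that tr(Σs) = N, i.e. unit average pixel
    variance, which keeps percent errors and SNR settings comparable across
    grid sizes.
    """
    if exponent <= 0:
        raise ValueError("exponent must be > 0")
    fb = RealFourier2D(grid.height, grid.width)
    f = fb.frequency
    lam = np.zeros(fb.n)
    nz = f > 0
    lam[nz] = f[nz] ** (-exponent)
    if lam.sum() > 0:
        lam *= fb.n / lam.sum()
    return SpectralCovariance(fb, lam, f, grid=grid)


def make_powerlaw_components(n: int, exponent: float = 2.0) -> SpectralCovariance:
    """Abstract n-component 1/f^exponent signal for spectral analysis.

    Component i carries frequency f_i = i/(2n) (i = 1..n, up to the
    Nyquist rate) and variance ∝ 1/f_i^exponent, normalized to tr(Σs) = n;
    the eigenbasis is the identity.  Unlike the spatial-grid constructor
    there is no DC component, so every component has positive variance and
    the whitening baseline exists for any M ≤ n.
    """
    if exponent <= 0:
        raise ValueError("exponent must be > 0")
    if n < 1:
        raise ValueError("n must be >= 1")
    f = np.arange(1, n + 1) / (2.0 * n)
    lam = f ** (-exponent)
    lam *= n / lam.sum()
    return SpectralCovariance(DenseBasis(np.eye(n)), lam, f)


def empirical_covariance(patches: np.ndarray, grid: GridGeometry | None = None) -> SpectralCovariance:
    """Eigendecompose the sample covariance of zero-meaned patches.

    ``patches`` is (n_samples, N).  Eigenvalues are sorted descending;
    values below 1e-12 of the largest are clipped to zero (PSD guard).
    The frequency index is the plain component rank.
    """
    x = np.asarray(patches, dtype=float)
    if x.ndim != 2:
        raise ValueError("patches must be a 2-D (n_samples, N) array")
    n = x.shape[1]
    cov = x.T @ x / x.shape[0]
    lam, vec = np.linalg.eigh(cov)
    order = np.argsort(lam)[::-1]
    lam, vec = lam[order], vec[:, order]
    cutoff = 1e-12 * max(lam.max(initial=0.0), 0.0)
    lam = np.where(lam < cutoff, 0.0, lam)
    return SpectralCovariance(DenseBasis(vec), lam, np.arange(n, dtype=float), grid=grid)


def sensory_noise_for_snr(
    signal: SpectralCovariance, blur: BlurModel, snr_db: float
) -> float:
    """Sensory noise variance giving 10·log10(tr(AΣsAᵀ)/(N σn²)) = snr_db."""
    t = float(np.sum(blur.spectral_gains**2 * signal.spectrum))
    if t <= 0:
        raise ValueError("blurred signal has zero power; sensory SNR undefined")
    return t / (signal.n * 10.0 ** (snr_db / 10.0))


def sensory_snr_db(signal: SpectralCovariance, blur: BlurModel, sensory_variance: float) -> float:
    """Measured sensory SNR in dB for a given noise variance."""
    t = float(np.sum(blur.spectral_gains**2 * signal.spectrum))
    return 10.0 * np.log10(t / (signal.n * sensory_variance))


def neural_power_budget(population_size: int, neural_variance: float, neural_snr_db: float) -> float:
    """Total response-power budget P = M σδ² 10^(SNR_dB/10).

    The budget scales linearly with M: adding neurons adds capacity.
    """
    if population_size < 1:
        raise ValueError("population_size must be >= 1")
    if neural_variance <= 0:
        raise ValueError("neural_variance must be > 0")
    return population_size * neural_variance * 10.0 ** (neural_snr_db / 10.0)


def capacity_bits(snr_db: float) -> float:
    """Gaussian-channel capacity ½·log2(1 + SNR) for an SNR given in dB."""
    return 0.5 * np.log2(1.0 + 10.0 ** (snr_db / 10.0))
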