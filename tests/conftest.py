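import numpy as np
import pytest

from popcode.basis import DenseBasis
from popcode.signal_model import (
    BlurModel,
    CodingProblem,
    GridGeometry,
    NoiseLevels,
    SpectralCovariance,
    make_powerlaw_spectrum,
)


@pytest.fixture
def diag_problem_factory():
    """Problems with an identity eigenbasis — spectra are directly visible."""

    def make(lam, a=None, sensory_variance=0.0, neural_variance=1.0, m=None, p=1.0):
        lam = np.asarray(lam, dtype=float)
        n = lam.size
        cov = SpectralCovariance(
            DenseBasis(np.eye(n)), lam, np.arange(n, dtype=float)
        )
        blur = BlurModel(np.asarray(a, dtype=float)) if a is not None else BlurModel.identity(n)
        return CodingProblem(
            cov, blur, NoiseLevels(sensory_variance, neural_variance),
            m if m is not None else n, p,
        )

    return make


@pytest.fixture
def random_problem_factory():
    """Random co-diagonal problems with a random orthonormal eigenbasis."""

    def make(rng, n=None, m=None):
        n = n or int(rng.integers(2, 9))
        m = m or int(rng.integers(1, n + 1))
        lam = np.sort(rng.uniform(0.05, 4.0, n))[::-1]
        q = np.linalg.qr(rng.standard_normal((n, n)))[0]
        cov = SpectralCovariance(DenseBasis(q), lam, np.arange(n, dtype=float))
        blur = BlurModel(rng.uniform(0.1, 1.5, n))
        noise = NoiseLevels(float(rng.uniform(0.0, 1.0)), float(rng.uniform(0.3, 2.0)))
        p = float(rng.uniform(0.5, 20.0))
        return CodingProblem(cov, blur, noise, m, p)

    return make


@pytest.fixture(scope="session")
def fovea_problem():
    """15×15 complete (1:1) retinal-style problem, 10 dB sensory and neural SNR."""
    grid = GridGeometry(15, 15)
    cov = make_powerlaw_spectrum(grid, 2.0)
    blur = BlurModel.gaussian(cov, 1.0)
    return CodingProblem.from_snr(cov, blur, 225, sensory_snr_db=10.0, neural_snr_db=10.0)
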