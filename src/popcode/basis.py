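"""Real orthonormal 2-D Fourier bases and dense eigenbases.

Signal covariances are kept in a co-diagonal spectral form Σ = E diag(λ) Eᵀ.
For stationary (translation-invariant) statistics on an H×W pixel lattice the
eigenbasis E is the real discrete Fourier basis: the DC vector followed by
cosine/sine pairs ordered by increasing spatial-frequency magnitude.  The
basis is generated column-on-demand so that large grids (e.g. 121×121,
N = 14,641) never require materializing the full N×N matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["RealFourier2D", "DenseBasis"]


def _canonical_pairs(h: int, w: int):
    """Enumerate canonical frequency representatives for an h×w grid.

    Each integer frequency (fy, fx) in [0,h)×[0,w) is conjugate to
    ((h−fy)%h, (w−fx)%w); one representative per conjugate pair is kept
    (the lexicographically smaller).  Self-conjugate frequencies (DC and
    Nyquist combinations) contribute a single cosine vector; all others a
    cosine/sine pair.
    """
    seen = set()
    reps = []
    for fy in range(h):
        for fx in range(w):
            conj = ((h - fy) % h, (w - fx) % w)
            key = min((fy, fx), conj)
            if key in seen:
                continue
            seen.add(key)
            fy_c, fx_c = key
            fy_s = fy_c if fy_c <= h / 2 else fy_c - h
            fx_s = fx_c if fx_c <= w / 2 else fx_c - w
            fmag = float(np.hypot(fy_s / h, fx_s / w))  # cycles / pixel
            self_conj = (fy_c, fx_c) == ((h - fy_c) % h, (w - fx_c) % w)
            reps.append((fmag, fy_c, fx_c, self_conj))
    reps.sort(key=lambda t: (t[0], t[1], t[2]))
    return reps


@dataclass(frozen=True)
class RealFourier2D:
    """Real orthonormal Fourier basis on an ``height``×``width`` lattice.

    Components are ordered DC first, then cos/sin pairs by increasing
    frequency magnitude with ties broken lexicographically on the canonical
    (fy, fx).  Pixels are flattened row-major (y major).
    """

    height: int
    width: int
    # per-component (fmag, fy, fx, phase) with phase 0=cos, 1=sin
    _components: tuple = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        if self.height < 1 or self.width < 1:
            raise ValueError("grid dimensions must be >= 1")
        comps = []
        for fmag, fy, fx, self_conj in _canonical_pairs(self.height, self.width):
            comps.append((fmag, fy, fx, 0))
            if not self_conj:
                comps.append((fmag, fy, fx, 1))
        object.__setattr__(self, "_components", tuple(comps))

    @property
    def n(self) -> int:
        return self.height * self.width

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n, self.n)

    @property
    def frequency(self) -> np.ndarray:
        """Spatial-frequency magnitude (cycles/pixel) of each component."""
        return np.array([c[0] for c in self._components])

    def take(self, indices) -> np.ndarray:
        """Columns of E for the given component indices, as an (N, k) array."""
        indices = np.atleast_1d(np.asarray(indices, dtype=int))
        n = self.n
        y = np.arange(self.height)
        x = np.arange(self.width)
        cols = np.empty((n, indices.size))
        for j, i in enumerate(indices):
            fmag, fy, fx, phase = self._components[i]
            ang = (2 * np.pi) * (
                (fy / self.height) * y[:, None] + (fx / self.width) * x[None, :]
            )
            v = np.sin(ang) if phase else np.cos(ang)
            v = v.ravel()
            nrm = np.linalg.norm(v)
            cols[:, j] = v / nrm
        return cols

    def full(self) -> np.ndarray:
        """The dense N×N basis matrix (use only for small grids)."""
        return self.take(np.arange(self.n))


@dataclass(frozen=True)
class DenseBasis:
    """An explicit orthonormal basis, e.g. from an empirical eigendecomposition."""

    matrix: np.ndarray

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError("basis matrix must be square")
        object.__setattr__(self, "matrix", m)

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.matrix.shape

    def take(self, indices) -> np.ndarray:
        indices = np.atleast_1d(np.asarray(indices, dtype=int))
        return self.matrix[:, indices]

    def full(self) -> np.ndarray:
        return self.matrix
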