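"""Spectral-stage analysis and receptive-field characterization.

`stage_spectra` lays out every stage of the coding pipeline component by
component — signal spectrum, blur MTF, blurred signal, sensory noise
floor, encoding gain, encoded response power, neural noise floor, decoding
gain and reconstructed variance — the view in which the water-filling
cutoff, half-whitening and whitening flatness are all visible.

`rf_summary` characterizes a receptive field (one row of W) by its peak,
its half-height center (the connected pixel region around the peak at
≥ half the peak weight), the center pixel count, and a cross-section
through the peak.  `adaptation_metric` compares mean center sizes across
two light levels (sensory SNRs).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .coding import DecoderSolution, EncoderSolution
from .signal_model import CodingProblem, GridGeometry

__all__ = [
    "StageSpectra",
    "ReceptiveFieldSummary",
    "stage_spectra",
    "rf_summary",
    "population_summaries",
    "adaptation_metric",
    "is_center_surround",
    "center_surround_fraction",
]


@dataclass(frozen=True)
class StageSpectra:
    """Per-component arrays for every stage of the pipeline."""

    frequency: np.ndarray
    signal: np.ndarray            # λ_i
    blur_gain: np.ndarray         # a_i
    blurred_signal: np.ndarray    # a_i² λ_i
    sensory_noise: np.ndarray     # σn² (flat)
    encoding_gain: np.ndarray     # g_i
    encoded_signal: np.ndarray    # p_i = g_i²(a_i²λ_i + σn²)
    neural_noise: np.ndarray      # σδ² (flat)
    decoding_gain: np.ndarray     # λ_i a_i g_i / (p_i + σδ²)
    reconstructed: np.ndarray     # variance of the reconstructed component

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {k: getattr(self, k) for k in self.__dataclass_fields__}
        )


def stage_spectra(
    problem: CodingProblem,
    encoder: EncoderSolution,
    decoder: DecoderSolution | None = None,
) -> StageSpectra:
    """Component-wise variances and gains at every stage for a factored encoder."""
    lam = problem.signal.spectrum
    a = problem.blur.spectral_gains
    sn2 = problem.noise.sensory_variance
    sd2 = problem.noise.neural_variance
    g = encoder.allocation.gains
    p = encoder.allocation.power
    dec_gain = np.zeros_like(lam)
    np.divide(lam * a * g, p + sd2, out=dec_gain)
    recon = dec_gain**2 * (p + sd2)
    return StageSpectra(
        frequency=problem.signal.frequency_index,
        signal=lam,
        blur_gain=a,
        blurred_signal=a**2 * lam,
        sensory_noise=np.full_like(lam, sn2),
        encoding_gain=g,
        encoded_signal=p,
        neural_noise=np.full_like(lam, sd2),
        decoding_gain=dec_gain,
        reconstructed=recon,
    )


@dataclass(frozen=True)
class ReceptiveFieldSummary:
    """Half-height-center characterization of a single receptive field."""

    peak: tuple[int, int]
    peak_value: float
    center_mask: np.ndarray          # boolean grid: the half-height region
    center_pixel_count: int
    cross_section: np.ndarray        # profile through the peak row (smoothed)
    cross_section_raw: np.ndarray
    polarity: np.ndarray             # sign map of the weights


def rf_summary(
    row: np.ndarray,
    geometry: GridGeometry,
    smooth_sigma: float = 0.5,
) -> ReceptiveFieldSummary:
    """Characterize one receptive field.

    The peak is the maximum-|weight| pixel (ties: lowest flat index); the
    center is the 8-connected component, containing the peak, of pixels
    whose weight (signed toward the peak's polarity) is at least half the
    peak magnitude.  The count is taken on the raw weights; smoothing
    (gaussian, σ=0.5 px) is applied to the displayed cross-section only.
    """
    w = np.asarray(row, dtype=float).reshape(geometry.height, geometry.width)
    if not np.any(w):
        raise ValueError("all-zero receptive field")
    flat_peak = int(np.argmax(np.abs(w)))
    py, px = divmod(flat_peak, geometry.width)
    peak_val = w[py, px]
    sign = 1.0 if peak_val >= 0 else -1.0
    mask = sign * w >= 0.5 * abs(peak_val)
    labels, _ = ndimage.label(mask, structure=np.ones((3, 3), dtype=int))
    center = labels == labels[py, px]
    raw_cs = w[py, :].copy()
    cs = ndimage.gaussian_filter1d(raw_cs, smooth_sigma) if smooth_sigma > 0 else raw_cs
    return ReceptiveFieldSummary(
        peak=(py, px),
        peak_value=float(peak_val),
        center_mask=center,
        center_pixel_count=int(center.sum()),
        cross_section=cs,
        cross_section_raw=raw_cs,
        polarity=np.sign(w),
    )


def population_summaries(W: np.ndarray, geometry: GridGeometry) -> list[ReceptiveFieldSummary]:
    """rf_summary for every row of an encoding matrix."""
    return [rf_summary(W[j], geometry) for j in range(W.shape[0])]


def typical_unit(summaries: list[ReceptiveFieldSummary], geometry: GridGeometry) -> int:
    """Index of the unit whose peak lies nearest the grid center."""
    cy, cx = (geometry.height - 1) / 2, (geometry.width - 1) / 2
    d = [((s.peak[0] - cy) ** 2 + (s.peak[1] - cx) ** 2) for s in summaries]
    return int(np.argmin(d))


def is_center_surround(row: np.ndarray, geometry: GridGeometry) -> bool:
    """Concentric ON-center/OFF-surround test for one receptive field.

    True when (i) the peak weight is positive (a positive half-height
    center) and (ii) the annulus two dilations beyond the center has a
    negative mean weight in *every* populated quadrant around the peak —
    which a difference-of-gaussians satisfies but an oriented (Gabor-like)
    or delocalized field does not.
    """
    s = rf_summary(row, geometry, smooth_sigma=0.0)
    if s.peak_value <= 0:
        return False
    w = np.asarray(row, dtype=float).reshape(geometry.height, geometry.width)
    dil = ndimage.binary_dilation(s.center_mask, np.ones((3, 3)), iterations=2)
    annulus = dil & ~s.center_mask
    if not annulus.any():
        return False
    py, px = s.peak
    yy, xx = np.meshgrid(
        np.arange(geometry.height), np.arange(geometry.width), indexing="ij"
    )
    for above in (False, True):
        for left in (False, True):
            sector = annulus & ((yy >= py) == above) & ((xx >= px) == left)
            if sector.any() and w[sector].mean() >= 0:
                return False
    return True


def center_surround_fraction(W: np.ndarray, geometry: GridGeometry) -> float:
    """Fraction of encoder rows classified as center-surround."""
    flags = [is_center_surround(W[j], geometry) for j in range(W.shape[0])]
    return float(np.mean(flags))


def adaptation_metric(
    summaries_low_snr: list[ReceptiveFieldSummary],
    summaries_high_snr: list[ReceptiveFieldSummary],
) -> float:
    """Percent growth of the mean half-height center size at low light.

    100·(mean_low/mean_high − 1): e.g. means of 8.8 vs 1.0 pixels → 780%.
    """
    if not summaries_low_snr or not summaries_high_snr:
        raise ValueError("empty population")
    lo = float(np.mean([s.center_pixel_count for s in summaries_low_snr]))
    hi = float(np.mean([s.center_pixel_count for s in summaries_high_snr]))
    return 100.0 * (lo / hi - 1.0)
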