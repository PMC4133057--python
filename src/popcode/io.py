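"""Configuration, persistence, images and report generation.

RunConfig validates a JSON/YAML run description and builds the
corresponding `CodingProblem`; solutions round-trip through a directory of
deterministic .npy files plus a JSON sidecar carrying metadata and a
content hash; reports are CSV tables (error-vs-population-size, stage
spectra, receptive-field summaries) and PNG panels rendered headlessly.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from pathlib import Path
from typing import Literal, Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .coding import DecoderSolution, EncoderSolution, PowerAllocation
from .shaping import ConstraintSpec, ShapingState
from .signal_model import (
    BlurModel,
    CodingProblem,
    GridGeometry,
    SpectralCovariance,
    empirical_covariance,
    make_powerlaw_spectrum,
)

__all__ = [
    "ConstraintConfig",
    "RunConfig",
    "load_config",
    "save_config",
    "build_problem",
    "resolve_population_size",
    "save_solution",
    "load_solution",
    "read_image",
    "write_image",
    "write_error_vs_population",
    "write_stage_spectra",
    "write_rf_summaries",
    "rf_mosaic_png",
    "tiling_png",
]


class ConstraintConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    kind: Literal["none", "weight_sparsity", "response_sparsity", "locality"] = "none"
    gamma: float = Field(0.1, ge=0)
    q: float = Field(0.5, gt=0, le=2)
    kappa: float = Field(0.5, gt=0)
    restarts: int = Field(1, ge=1)


class RunConfig(BaseModel):
    """Validated description of one solve/shape run."""

    model_config = ConfigDict(extra="forbid")

    height: int = Field(..., ge=1)
    width: int = Field(..., ge=1)
    ratio: Optional[float] = Field(None, gt=0)
    population_size: Optional[int] = Field(None, ge=1)
    exponent: float = Field(2.0, gt=0)
    covariance_path: Optional[str] = None
    blur_sigma: float = Field(1.0, ge=0)
    sensory_snr_db: float = 0.0
    neural_snr_db: float = 10.0
    neural_noise_variance: float = Field(1.0, gt=0)
    sensory_snr_limits: tuple[float, float] = (-10.0, 20.0)
    constraint: ConstraintConfig = ConstraintConfig()
    seed: int = 0
    output_dir: str = "runs"

    @model_validator(mode="after")
    def _check(self):
        if (self.ratio is None) == (self.population_size is None):
            raise ValueError("specify exactly one of 'ratio' or 'population_size'")
        lo, hi = self.sensory_snr_limits
        if not (lo <= self.sensory_snr_db <= hi):
            raise ValueError(
                f"sensory_snr_db={self.sensory_snr_db} outside declared range "
                f"[{lo}, {hi}]"
            )
        return self


def load_config(path) -> RunConfig:
    """Read a RunConfig from JSON or YAML (by extension)."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() in (".yaml", ".yml"):
        import yaml

        data = yaml.safe_load(text)
    else:
        data = json.loads(text)
    return RunConfig.model_validate(data)


def save_config(config: RunConfig, path) -> None:
    path = Path(path)
    data = config.model_dump()
    if path.suffix.lower() in (".yaml", ".yml"):
        import yaml

        path.write_text(yaml.safe_dump(data, sort_keys=True))
    else:
        path.write_text(json.dumps(data, indent=2, sort_keys=True))


def resolve_population_size(config: RunConfig) -> int:
    n = config.height * config.width
    if config.population_size is not None:
        return config.population_size
    return int(round(n / config.ratio))


def build_problem(config: RunConfig) -> CodingProblem:
    """Instantiate the CodingProblem a RunConfig describes."""
    grid = GridGeometry(config.height, config.width)
    if config.covariance_path is not None:
        patches = np.load(config.covariance_path)
        cov = empirical_covariance(patches, grid=grid)
    else:
        cov = make_powerlaw_spectrum(grid, config.exponent)
    blur = (
        BlurModel.gaussian(cov, config.blur_sigma)
        if config.blur_sigma > 0
        else BlurModel.identity(cov.n)
    )
    return CodingProblem.from_snr(
        cov,
        blur,
        resolve_population_size(config),
        config.sensory_snr_db,
        config.neural_snr_db,
        config.neural_noise_variance,
    )


def build_constraint(config: RunConfig, samples: np.ndarray | None = None) -> ConstraintSpec:
    c = config.constraint
    return ConstraintSpec(kind=c.kind, gamma=c.gamma, q=c.q, samples=samples)


# ---------------------------------------------------------------------------
# persistence

def _array_hash(arrays: dict[str, np.ndarray]) -> str:
    h = hashlib.sha256()
    for name in sorted(arrays):
        h.update(name.encode())
        h.update(np.ascontiguousarray(arrays[name]).tobytes())
    return h.hexdigest()


def save_solution(
    directory,
    encoder: EncoderSolution,
    decoder: DecoderSolution | None = None,
    state: ShapingState | None = None,
    metadata: dict | None = None,
) -> Path:
    """Persist an encoder (+decoder/shaping state) as .npy files + meta.json.

    Individual .npy files are byte-deterministic (unlike zipped .npz), so a
    save→load→save round trip reproduces identical bytes.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    arrays = {
        "V": encoder.V,
        "power": encoder.allocation.power,
        "gains": encoder.allocation.gains,
        "active": encoder.allocation.active,
    }
    if decoder is not None:
        arrays["G"] = decoder.G
    if state is not None:
        arrays["history"] = np.asarray(state.history, dtype=float)
    for name, arr in arrays.items():
        np.save(directory / f"{name}.npy", np.ascontiguousarray(arr))
    meta = dict(metadata or {})
    meta["content_hash"] = _array_hash(arrays)
    meta["arrays"] = sorted(arrays)
    if encoder.allocation.water_level is not None:
        meta["water_level"] = encoder.allocation.water_level
    if decoder is not None:
        meta["expected_mse"] = decoder.expected_mse
        meta["percent_error"] = decoder.percent_error
    if state is not None:
        meta["converged"] = bool(state.converged)
        meta["individual_power_violation"] = state.individual_power_violation
        meta["constraint_cost"] = state.constraint_cost
    (directory / "meta.json").write_text(json.dumps(meta, indent=2, sort_keys=True))
    return directory


def load_solution(directory) -> dict:
    """Load a persisted solution; warns if the content hash does not match."""
    directory = Path(directory)
    meta_path = directory / "meta.json"
    if not meta_path.exists():
        raise FileNotFoundError(f"no solution at {directory} (missing meta.json)")
    meta = json.loads(meta_path.read_text())
    arrays = {name: np.load(directory / f"{name}.npy") for name in meta["arrays"]}
    if _array_hash(arrays) != meta.get("content_hash"):
        warnings.warn(
            f"content hash mismatch loading {directory}; arrays may have been edited",
            RuntimeWarning,
            stacklevel=2,
        )
    return {"meta": meta, **arrays}


def rebuild_encoder(bundle: dict, problem: CodingProblem) -> EncoderSolution:
    alloc = PowerAllocation(
        power=bundle["power"],
        gains=bundle["gains"],
        active=bundle["active"].astype(int),
        water_level=bundle["meta"].get("water_level"),
    )
    return EncoderSolution(
        V=bundle["V"], allocation=alloc, basis=problem.signal, problem=problem
    )


# ---------------------------------------------------------------------------
# images

def read_image(path) -> np.ndarray:
    """Read a grayscale PNG/PGM (8- or 16-bit) as zero-mean floats in [−1, 1]."""
    from PIL import Image

    img = Image.open(path)
    arr = np.asarray(img, dtype=float)
    if arr.ndim == 3:
        arr = arr.mean(axis=2)
    scale = 65535.0 if arr.max() > 255 else 255.0
    arr = arr / scale
    return arr - arr.mean()


def write_image(path, array: np.ndarray) -> None:
    """Write a float array as an 8-bit grayscale PNG/PGM, min-max scaled."""
    from PIL import Image

    a = np.asarray(array, dtype=float)
    rng = a.max() - a.min()
    a = (a - a.min()) / rng if rng > 0 else np.zeros_like(a)
    Image.fromarray((a * 255).astype(np.uint8), mode="L").save(path)


# ---------------------------------------------------------------------------
# reports

def write_error_vs_population(path, rows: list[dict]) -> pd.DataFrame:
    """CSV with one row per population size; percent errors to 1 d.p."""
    df = pd.DataFrame(
        rows, columns=["population_size", "ratio", "percent_error_optimal",
                       "percent_error_whitening", "percent_error_limit"]
    )
    for col in df.columns:
        if col.startswith("percent_error"):
            df[col] = df[col].astype(float).round(1)
    df.to_csv(path, index=False)
    return df


def write_stage_spectra(path, spectra) -> pd.DataFrame:
    df = spectra.to_dataframe()
    df.to_csv(path, index=False)
    return df


def write_rf_summaries(path, summaries) -> pd.DataFrame:
    df = pd.DataFrame(
        [
            {
                "unit": j,
                "peak_y": s.peak[0],
                "peak_x": s.peak[1],
                "peak_value": s.peak_value,
                "center_pixel_count": s.center_pixel_count,
            }
            for j, s in enumerate(summaries)
        ]
    )
    df.to_csv(path, index=False)
    return df


def rf_mosaic_png(path, W: np.ndarray, geometry: GridGeometry, n_show: int = 25) -> None:
    """Tile the first n_show receptive fields into one PNG panel."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    n_show = min(n_show, W.shape[0])
    cols = int(np.ceil(np.sqrt(n_show)))
    rows = int(np.ceil(n_show / cols))
    fig, axes = plt.subplots(rows, cols, figsize=(1.2 * cols, 1.2 * rows))
    axes = np.atleast_1d(axes).ravel()
    vmax = np.abs(W[:n_show]).max()
    for ax in axes:
        ax.axis("off")
    for j in range(n_show):
        axes[j].imshow(
            W[j].reshape(geometry.height, geometry.width),
            cmap="gray", vmin=-vmax, vmax=vmax, interpolation="nearest",
        )
    fig.savefig(path, dpi=100, bbox_inches="tight")
    plt.close(fig)


def tiling_png(path, summaries, geometry: GridGeometry) -> None:
    """Overlay all half-height center contours on the pixel lattice."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4, 4))
    for s in summaries:
        ax.contour(s.center_mask.astype(float), levels=[0.5], colors="k", linewidths=0.7)
    ax.set_xticks(np.arange(-0.5, geometry.width, 1), minor=True)
    ax.set_yticks(np.arange(-0.5, geometry.height, 1), minor=True)
    ax.grid(which="minor", color="orange", linewidth=0.3)
    ax.set_aspect("equal")
    fig.savefig(path, dpi=100, bbox_inches="tight")
    plt.close(fig)
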