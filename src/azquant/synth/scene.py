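"""Common scene description, PSF and noise forward model.

The forward model is deliberately simple: ideal geometry is rasterised at
pixel centres, convolved with an isotropic Gaussian point-spread function,
a constant background is added, and noise is applied last.  Physical
positions are pixel-centre index × pixel size; pixel indices are 0-based.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
from scipy import ndimage

VALID_NOISE_MODELS = ("none", "poisson", "gaussian")

# Default PSF scales: confocal-like for droplet/puncta scenes, STED-like
# for the side-view scenes sampled at 22.5 nm/px.
DEFAULT_CONFOCAL_PSF_NM = 90.0
DEFAULT_STED_PSF_NM = 30.0


@dataclass(frozen=True)
class SceneSpec:
    """Rendering context shared by all generators.

    Parameters
    ----------
    shape : (rows, cols) in pixels.
    pixel_size_nm : physical pixel pitch.
    frame_interval_s : time between frames.
    psf_sigma_nm : Gaussian PSF sigma; 0 disables blurring.
    background_level : constant background added to every pixel.
    noise_model : "none", "poisson" (on expected photon counts) or
        "gaussian" (additive, sd = ``noise_sd``).
    seed : seed for the scene's private random generator.
    """

    shape: tuple[int, int] = (128, 128)
    pixel_size_nm: float = 100.0
    frame_interval_s: float = 1.0
    psf_sigma_nm: float = DEFAULT_CONFOCAL_PSF_NM
    background_level: float = 0.0
    noise_model: str = "none"
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.pixel_size_nm > 0):
            raise ValueError("pixel_size_nm must be > 0")
        if not (self.frame_interval_s > 0):
            raise ValueError("frame_interval_s must be > 0")
        if self.psf_sigma_nm < 0:
            raise ValueError("psf_sigma_nm must be >= 0")
        if self.noise_model not in VALID_NOISE_MODELS:
            raise ValueError(f"noise_model must be one of {VALID_NOISE_MODELS}")

    @property
    def psf_sigma_px(self) -> float:
        return self.psf_sigma_nm / self.pixel_size_nm

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def apply_psf(image: np.ndarray, scene: SceneSpec) -> np.ndarray:
    if scene.psf_sigma_px > 0:
        return ndimage.gaussian_filter(image, sigma=scene.psf_sigma_px, mode="constant")
    return image


def apply_noise(image: np.ndarray, scene: SceneSpec, rng: np.random.Generator) -> np.ndarray:
    if scene.noise_model == "poisson":
        return rng.poisson(np.clip(image, 0, None)).astype(float)
    if scene.noise_model == "gaussian":
        return image + rng.normal(0.0, scene.noise_sd, size=image.shape)
    return image


@dataclass
class GroundTruth:
    """Record of every planted signal source of a synthetic dataset.

    ``objects`` is a per-frame table (one row per rendered object per
    frame); ``events`` lists planted fusion/fission or bleach events;
    ``params`` holds scalar truth (rates, offsets, group means);
    ``warnings`` collects generator diagnostics such as unintended
    overlaps.
    """

    objects: pd.DataFrame = field(default_factory=pd.DataFrame)
    events: list[dict] = field(default_factory=list)
    params: dict[str, Any] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)

    def write(self, directory: str | Path, stem: str = "ground_truth") -> None:
        """Write objects as CSV, events/params/warnings as JSON."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        if len(self.objects):
            self.objects.to_csv(directory / f"{stem}_objects.csv", index=False)
        payload = {
            "events": self.events,
            "params": _jsonable(self.params),
            "warnings": self.warnings,
        }
        (directory / f"{stem}.json").write_text(json.dumps(payload, indent=2))


def _jsonable(obj: Any) -> Any:
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj
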