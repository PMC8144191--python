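"""Synthetic confocal fields of synaptic puncta with known intensities.

Channel 0 is the synaptic-vesicle marker (uniform-intensity disks used to
define ROIs); channel 1 is the protein of interest, rendered as disks with
specified per-punctum means on an optional background field.  Ground truth
stores the punctum label mask and every true mean, with background
recorded separately (the additive model keeps true means well defined on
any background).
"""

from __future__ import annotations

import math
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from azquant.io import ImageStack
from azquant.synth.scene import GroundTruth, SceneSpec, apply_noise, apply_psf


def render_confocal_field(
    scene: SceneSpec,
    n_puncta: int,
    punctum_intensities: float | Sequence[float],
    punctum_radius_px: float = 3.0,
    marker_intensity: float = 120.0,
    background: float | Callable[[np.ndarray, np.ndarray], np.ndarray] = 0.0,
    min_separation_px: float | None = None,
    edge_margin_px: float | None = None,
    max_tries: int = 5000,
) -> tuple[ImageStack, GroundTruth]:
    """Render a 2-channel punctum field and its ground truth.

    ``punctum_intensities`` is a scalar (all puncta equal) or one value per
    punctum.  ``background`` is a constant or a callable ``f(yy, xx)``
    evaluated on the pixel grid and added to the protein channel only.
    Puncta are placed uniformly at random without overlap; failure to
    place them within ``max_tries`` raises ``RuntimeError``.
    """
    rows, cols = scene.shape
    rng = scene.rng()
    if np.isscalar(punctum_intensities):
        intensities = np.full(n_puncta, float(punctum_intensities))
    else:
        intensities = np.asarray(punctum_intensities, dtype=float)
        if intensities.size != n_puncta:
            raise ValueError("need one intensity per punctum")

    if min_separation_px is None:
        min_separation_px = 2.0 * punctum_radius_px + 2.0 + 4.0 * scene.psf_sigma_px
    margin = edge_margin_px if edge_margin_px is not None else punctum_radius_px + 2.0 + 3.0 * scene.psf_sigma_px

    centers: list[tuple[float, float]] = []
    for _ in range(n_puncta):
        for attempt in range(max_tries):
            cx = rng.uniform(margin, cols - 1 - margin)
            cy = rng.uniform(margin, rows - 1 - margin)
            if all(math.hypot(cx - x, cy - y) >= min_separation_px for x, y in centers):
                centers.append((cx, cy))
                break
        else:
            raise RuntimeError("punctum density too high to place without overlap")

    yy, xx = np.mgrid[0:rows, 0:cols]
    marker = np.zeros((rows, cols))
    protein = np.zeros((rows, cols))
    label_mask = np.zeros((rows, cols), dtype=int)
    records = []
    for i, ((cx, cy), inten) in enumerate(zip(centers, intensities), start=1):
        disk = (xx - cx) ** 2 + (yy - cy) ** 2 <= punctum_radius_px**2
        marker[disk] = marker_intensity
        protein[disk] = inten
        label_mask[disk] = i
        records.append(
            {
                "punctum_id": i,
                "cx_px": cx,
                "cy_px": cy,
                "true_mean": float(inten),
                "area_px": int(disk.sum()),
            }
        )

    bg = background(yy, xx) if callable(background) else np.full((rows, cols), float(background))
    rng_noise = np.random.default_rng(rng.integers(0, 2**31))
    marker_out = apply_noise(apply_psf(marker, scene) + scene.background_level, scene, rng_noise)
    protein_out = apply_noise(apply_psf(protein, scene) + bg + scene.background_level, scene, rng_noise)

    truth = GroundTruth(
        objects=pd.DataFrame(records),
        params={
            "label_mask": label_mask,
            "marker_intensity": marker_intensity,
            "punctum_radius_px": punctum_radius_px,
            "background_is_constant": not callable(background),
            "seed": scene.seed,
        },
    )
    stack = ImageStack(
        np.stack([marker_out, protein_out], axis=-1)[None],
        pixel_size_nm=scene.pixel_size_nm,
        frame_interval_s=scene.frame_interval_s,
    )
    return stack, truth


def simulate_confocal_cohort(
    scene: SceneSpec,
    group_ratios: dict[str, float],
    n_cultures: int = 3,
    images_per_group: int = 5,
    n_puncta: int = 12,
    base_intensity: float = 100.0,
    culture_scale_sd: float = 0.0,
    punctum_cv: float = 0.0,
    seed: int = 0,
) -> tuple[list[dict], GroundTruth]:
    """Simulate a multi-culture imaging cohort with planted group effects.

    Each culture gets every group; a group's true per-punctum mean is
    ``base_intensity * group_ratios[group]`` scaled by a per-culture
    factor (lognormal-ish, sd ``culture_scale_sd``), with optional
    per-punctum variability ``punctum_cv``.  Returns a list of records
    ``{"stack", "truth", "culture", "group", "image"}`` plus cohort-level
    ground truth.
    """
    rng = np.random.default_rng(seed)
    records = []
    for c in range(n_cultures):
        culture_factor = math.exp(rng.normal(0.0, culture_scale_sd)) if culture_scale_sd > 0 else 1.0
        for group, ratio in group_ratios.items():
            for img in range(images_per_group):
                mean = base_intensity * ratio * culture_factor
                if punctum_cv > 0:
                    intensities = rng.normal(mean, punctum_cv * mean, size=n_puncta)
                    intensities = np.clip(intensities, 0.0, None)
                else:
                    intensities = np.full(n_puncta, mean)
                field_scene = SceneSpec(
                    shape=scene.shape,
                    pixel_size_nm=scene.pixel_size_nm,
                    frame_interval_s=scene.frame_interval_s,
                    psf_sigma_nm=scene.psf_sigma_nm,
                    background_level=scene.background_level,
                    noise_model=scene.noise_model,
                    noise_sd=scene.noise_sd,
                    seed=int(rng.integers(0, 2**31)),
                )
                stack, truth = render_confocal_field(
                    field_scene, n_puncta=n_puncta, punctum_intensities=intensities
                )
                records.append(
                    {
                        "stack": stack,
                        "truth": truth,
                        "culture": f"culture{c + 1}",
                        "group": group,
                        "image": f"c{c + 1}_{group}_{img}",
                    }
                )
    cohort_truth = GroundTruth(
        params={
            "group_ratios": dict(group_ratios),
            "base_intensity": base_intensity,
            "n_cultures": n_cultures,
            "images_per_group": images_per_group,
            "seed": seed,
        }
    )
    return records, cohort_truth
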