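"""Synthetic side-view synapses for STED line-profile analysis.

Geometry (all along the profile axis, positive pointing away from the
vesicle cloud): the marker bar sits at the image centre, tangent to the
edge of a broad vesicle cloud whose centre lies one cloud half-width
behind it; the protein of interest peaks at a configurable signed offset
from the marker, optionally with decoy peaks planted outside the
measurement window.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from azquant.io import ImageStack
from azquant.sted import IntensityProfile, ProfileLine
from azquant.synth.scene import GroundTruth, SceneSpec, apply_noise, apply_psf

FWHM_TO_SIGMA = 1.0 / (2.0 * math.sqrt(2.0 * math.log(2.0)))

CH_VESICLE, CH_MARKER, CH_PROTEIN = 0, 1, 2


@dataclass(frozen=True)
class SideViewSpec:
    """Signal layout of one synthetic side-view synapse."""

    vesicle_cloud_width_nm: float = 400.0  # FWHM; must exceed 300 nm
    vesicle_peak_intensity: float = 150.0
    marker_bar_length_nm: float = 500.0  # FWHM along the bar
    marker_bar_width_nm: float = 100.0  # FWHM across the bar (profile axis)
    marker_peak_intensity: float = 200.0
    protein_offset_nm: float = 0.0
    protein_peak_intensity: float = 180.0
    protein_spot_sigma_nm: float = 60.0
    decoy_peaks: tuple[tuple[float, float], ...] = ()  # (offset_nm, intensity)
    axis_angle_rad: float = 0.0
    # set True to deliberately plant a synapse that fails qualification
    allow_unqualifiable: bool = False

    def __post_init__(self) -> None:
        if not (self.vesicle_cloud_width_nm > 300.0) and not self.allow_unqualifiable:
            raise ValueError(
                "vesicle_cloud_width_nm must exceed 300 nm (qualification criterion); "
                "pass allow_unqualifiable=True to plant a failing example"
            )
        if self.marker_bar_length_nm <= self.marker_bar_width_nm:
            raise ValueError("marker bar must be longer than it is wide")


def _decoy_records(spec: SideViewSpec, window_nm: float = 100.0) -> list[dict]:
    return [
        {
            "offset_nm": float(off),
            "intensity": float(inten),
            "in_window": bool(abs(off) <= window_nm),
        }
        for off, inten in spec.decoy_peaks
    ]


def render_sideview_image(scene: SceneSpec, spec: SideViewSpec) -> tuple[ImageStack, GroundTruth]:
    """Render a 3-channel side-view image (vesicle, marker, protein).

    The marker centroid is at the image centre; ground truth records the
    profile line (centre + axis angle) and the true peak positions along
    it (marker at 0, protein at ``protein_offset_nm``).
    """
    rows, cols = scene.shape
    px = scene.pixel_size_nm
    cx, cy = (cols - 1) / 2.0, (rows - 1) / 2.0
    a = spec.axis_angle_rad
    ux, uy = math.cos(a), math.sin(a)

    yy, xx = np.mgrid[0:rows, 0:cols]
    # signed coordinates (nm) along the profile axis (p) and across it (q),
    # relative to the marker centre
    p = ((xx - cx) * ux + (yy - cy) * uy) * px
    q = (-(xx - cx) * uy + (yy - cy) * ux) * px

    half_cloud = spec.vesicle_cloud_width_nm / 2.0
    sig_cloud = spec.vesicle_cloud_width_nm * FWHM_TO_SIGMA
    vesicle = spec.vesicle_peak_intensity * np.exp(
        -(((p + half_cloud) ** 2) + q**2) / (2.0 * sig_cloud**2)
    )

    sig_across = spec.marker_bar_width_nm * FWHM_TO_SIGMA
    sig_along = spec.marker_bar_length_nm * FWHM_TO_SIGMA
    marker = spec.marker_peak_intensity * np.exp(
        -(p**2) / (2.0 * sig_across**2) - (q**2) / (2.0 * sig_along**2)
    )

    sig_prot = spec.protein_spot_sigma_nm
    protein = spec.protein_peak_intensity * np.exp(
        -((p - spec.protein_offset_nm) ** 2 + q**2) / (2.0 * sig_prot**2)
    )
    for off, inten in spec.decoy_peaks:
        protein = protein + inten * np.exp(-((p - off) ** 2 + q**2) / (2.0 * sig_prot**2))

    rng = scene.rng()
    channels = []
    for img in (vesicle, marker, protein):
        channels.append(apply_noise(apply_psf(img, scene) + scene.background_level, scene, rng))
    data = np.stack(channels, axis=-1)[None]

    truth = GroundTruth(
        params={
            "line_center_xy": (cx, cy),
            "line_angle_rad": a,
            "marker_true_pos_nm": 0.0,
            "protein_true_pos_nm": float(spec.protein_offset_nm),
            "protein_true_intensity": float(spec.protein_peak_intensity),
            "cloud_center_pos_nm": -half_cloud,
            "cloud_fwhm_nm": float(spec.vesicle_cloud_width_nm),
            "decoys": _decoy_records(spec),
            "pixel_size_nm": px,
            "seed": scene.seed,
        }
    )
    stack = ImageStack(data, pixel_size_nm=px, frame_interval_s=scene.frame_interval_s)
    return stack, truth


def simulate_sideview_profile(
    spec: SideViewSpec,
    pixel_size_nm: float = 22.5,
    length_nm: float = 1000.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[IntensityProfile, GroundTruth]:
    """Analytic 3-channel line profile of a side-view synapse.

    Equivalent to extracting the profile from a rendered image along the
    true line, but computed in closed form; used for fast randomized
    checks of the peak-measurement window logic.
    """
    n = int(math.floor(length_nm / pixel_size_nm)) + 1
    pos = (np.arange(n) - (n - 1) / 2.0) * pixel_size_nm

    half_cloud = spec.vesicle_cloud_width_nm / 2.0
    sig_cloud = spec.vesicle_cloud_width_nm * FWHM_TO_SIGMA
    vesicle = spec.vesicle_peak_intensity * np.exp(-((pos + half_cloud) ** 2) / (2.0 * sig_cloud**2))
    sig_across = spec.marker_bar_width_nm * FWHM_TO_SIGMA
    marker = spec.marker_peak_intensity * np.exp(-(pos**2) / (2.0 * sig_across**2))
    sig_prot = spec.protein_spot_sigma_nm
    protein = spec.protein_peak_intensity * np.exp(
        -((pos - spec.protein_offset_nm) ** 2) / (2.0 * sig_prot**2)
    )
    for off, inten in spec.decoy_peaks:
        protein = protein + inten * np.exp(-((pos - off) ** 2) / (2.0 * sig_prot**2))

    values = np.stack([vesicle, marker, protein], axis=1)
    if noise_sd > 0:
        values = values + np.random.default_rng(seed).normal(0.0, noise_sd, size=values.shape)

    truth = GroundTruth(
        params={
            "marker_true_pos_nm": 0.0,
            "protein_true_pos_nm": float(spec.protein_offset_nm),
            "decoys": _decoy_records(spec),
            "pixel_size_nm": pixel_size_nm,
        }
    )
    return IntensityProfile(positions_nm=pos, values=values, pixel_size_nm=pixel_size_nm), truth


def true_profile_line(scene: SceneSpec, spec: SideViewSpec) -> ProfileLine:
    """The ground-truth measurement line for a rendered side view."""
    rows, cols = scene.shape
    return ProfileLine(
        center_xy=((cols - 1) / 2.0, (rows - 1) / 2.0),
        angle_rad=spec.axis_angle_rad,
    )
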