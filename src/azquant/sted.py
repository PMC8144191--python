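"""STED side-view synapse line-profile analysis.

A side-view synapse is one whose active-zone / postsynaptic-density marker
appears as an elongated bar at the edge of the (confocal) vesicle cloud.
Quantification samples a 1 um-long, 250 nm-wide profile perpendicular to
the marker bar through its centre, applies a five-pixel rolled average,
takes the marker peak as the profile argmax, and measures the protein of
interest as the maximum intensity within +/-100 nm of the marker peak.
Profile positions are signed nm along the line, positive pointing away
from the vesicle cloud.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import measure

from azquant.io import ImageStack
from azquant._segment import threshold_image

DEFAULT_PROFILE_LENGTH_NM = 1000.0
DEFAULT_PROFILE_WIDTH_NM = 250.0
DEFAULT_WINDOW_NM = 100.0
DEFAULT_SMOOTH_PX = 5


@dataclass(frozen=True)
class ProfileLine:
    """Profile geometry: centre (x=col, y=row in px) and axis angle.

    ``angle_rad`` is the direction of increasing profile position in image
    xy coordinates; by convention it points away from the vesicle cloud.
    """

    center_xy: tuple[float, float]
    angle_rad: float
    length_nm: float = DEFAULT_PROFILE_LENGTH_NM
    width_nm: float = DEFAULT_PROFILE_WIDTH_NM


@dataclass
class IntensityProfile:
    """Width-averaged line profile; values is (n_positions, n_channels)."""

    positions_nm: np.ndarray
    values: np.ndarray
    pixel_size_nm: float

    def channel(self, c: int) -> np.ndarray:
        return self.values[:, c]


@dataclass
class PeakMeasurement:
    marker_peak_pos_nm: float
    protein_peak_pos_nm: float
    protein_peak_intensity: float
    protein_peak_intensity_raw: float
    peak_distance_nm: float
    window_nm: float
    smoothing_window_px: int


@dataclass
class QualificationResult:
    passed: bool
    cloud_fwhm_nm: float
    marker_elongation: float
    marker_angle_to_line_deg: float
    edge_fraction: float
    reasons: list[str] = field(default_factory=list)


@dataclass
class DensityObject:
    id: int
    centroid_rc: tuple[float, float]
    area_um2: float
    mean_intensity: float


def extract_profile(stack: ImageStack, line: ProfileLine) -> IntensityProfile:
    """Sample a width-averaged intensity profile along ``line``.

    Positions run at pixel pitch from -length/2 to +length/2; at each
    position the value is the mean of bilinearly interpolated samples
    taken at pixel pitch across the profile width, identically for every
    channel.  A line that exits the image raises ``ValueError``.
    """
    px = stack.pixel_size_nm
    n_pos = int(math.floor(line.length_nm / px)) + 1
    n_wid = max(int(math.floor(line.width_nm / px)) + 1, 1)
    positions = (np.arange(n_pos) - (n_pos - 1) / 2.0) * px
    widths = (np.arange(n_wid) - (n_wid - 1) / 2.0) * px

    ux, uy = math.cos(line.angle_rad), math.sin(line.angle_rad)
    vx, vy = -uy, ux
    cx, cy = line.center_xy
    pp, ww = np.meshgrid(positions / px, widths / px, indexing="ij")
    xs = cx + pp * ux + ww * vx
    ys = cy + pp * uy + ww * vy

    rows, cols = stack.shape_rc
    if xs.min() < 0 or ys.min() < 0 or xs.max() > cols - 1 or ys.max() > rows - 1:
        raise ValueError("profile line exits the image")

    out = np.empty((n_pos, stack.n_channels))
    for c in range(stack.n_channels):
        samples = ndimage.map_coordinates(
            stack.data[0, :, :, c], np.array([ys.ravel(), xs.ravel()]), order=1
        ).reshape(n_pos, n_wid)
        out[:, c] = samples.mean(axis=1)
    return IntensityProfile(positions_nm=positions, values=out, pixel_size_nm=px)


def smooth_profile(values: np.ndarray, window_px: int = DEFAULT_SMOOTH_PX) -> np.ndarray:
    """Centred moving average; edge windows shrink to the available span."""
    if window_px % 2 == 0 or window_px < 1:
        raise ValueError("smoothing window must be a positive odd integer")
    values = np.asarray(values, dtype=float)
    half = window_px // 2
    n = values.size
    cumsum = np.concatenate(([0.0], np.cumsum(values)))
    lo = np.maximum(np.arange(n) - half, 0)
    hi = np.minimum(np.arange(n) + half + 1, n)
    return (cumsum[hi] - cumsum[lo]) / (hi - lo)


def measure_peaks(
    profile: IntensityProfile,
    marker_channel: int,
    protein_channel: int,
    window_nm: float = DEFAULT_WINDOW_NM,
    smooth_px: int = DEFAULT_SMOOTH_PX,
) -> PeakMeasurement:
    """Marker peak (argmax) and windowed protein peak on smoothed profiles.

    The protein peak is the maximum of the smoothed protein profile among
    positions within ``window_nm`` of the marker peak; a marker-peak tie
    is broken toward the vesicle cloud (lower position), a protein tie
    toward the marker peak.
    """
    pos = profile.positions_nm
    marker = smooth_profile(profile.channel(marker_channel), smooth_px)
    protein = smooth_profile(profile.channel(protein_channel), smooth_px)
    raw_protein = profile.channel(protein_channel)

    m_idx = int(np.argmax(marker))  # first max = toward the cloud
    m_pos = pos[m_idx]

    in_window = np.abs(pos - m_pos) <= window_nm + 1e-9
    if not in_window.any():
        raise ValueError("empty measurement window around the marker peak")
    idxs = np.flatnonzero(in_window)
    vals = protein[idxs]
    best = vals.max()
    ties = idxs[vals == best]
    p_idx = int(ties[np.argmin(np.abs(pos[ties] - m_pos))])

    return PeakMeasurement(
        marker_peak_pos_nm=float(m_pos),
        protein_peak_pos_nm=float(pos[p_idx]),
        protein_peak_intensity=float(protein[p_idx]),
        protein_peak_intensity_raw=float(raw_protein[p_idx]),
        peak_distance_nm=float(abs(pos[p_idx] - m_pos)),
        window_nm=window_nm,
        smoothing_window_px=smooth_px,
    )


def _fwhm_nm(positions: np.ndarray, values: np.ndarray) -> tuple[float, float]:
    """(FWHM, centre position) of the dominant peak, by linear interpolation."""
    i_max = int(np.argmax(values))
    vmax = values[i_max]
    if vmax <= 0:
        return 0.0, float(positions[i_max])
    half = vmax / 2.0
    left = positions[0]
    for i in range(i_max, 0, -1):
        if values[i - 1] < half <= values[i]:
            f = (half - values[i - 1]) / (values[i] - values[i - 1])
            left = positions[i - 1] + f * (positions[i] - positions[i - 1])
            break
    right = positions[-1]
    for i in range(i_max, len(values) - 1):
        if values[i + 1] < half <= values[i]:
            f = (values[i] - half) / (values[i] - values[i + 1])
            right = positions[i] + f * (positions[i + 1] - positions[i])
            break
    above = values >= half
    centre = float(np.average(positions[above], weights=values[above]))
    return float(right - left), centre


def qualify_sideview(
    vesicle_image: np.ndarray,
    marker_image: np.ndarray,
    line: ProfileLine,
    pixel_size_nm: float,
    min_cloud_fwhm_nm: float = 300.0,
    min_elongation: float = 2.0,
    angle_tolerance_deg: float = 30.0,
    edge_fraction_range: tuple[float, float] = (0.25, 1.0),
) -> QualificationResult:
    """Decide whether a candidate synapse qualifies as a side view.

    Criteria: (a) vesicle-cloud FWHM along the profile > ``min_cloud_fwhm_nm``
    (the cloud is imaged in confocal mode); (b) the marker object is
    elongated (major/minor >= ``min_elongation``) with its major axis
    perpendicular to the profile within ``angle_tolerance_deg``; (c) the
    marker centroid sits at the cloud edge, between 25% and 100% of the
    cloud half-width from the cloud centre.
    """
    if vesicle_image.shape != marker_image.shape:
        raise ValueError("vesicle and marker channels must have the same shape")
    reasons: list[str] = []

    stack = ImageStack(
        np.stack([vesicle_image, marker_image], axis=-1)[None],
        pixel_size_nm=pixel_size_nm,
    )
    profile = extract_profile(stack, line)
    fwhm, cloud_centre = _fwhm_nm(profile.positions_nm, profile.channel(0))
    if not (fwhm > min_cloud_fwhm_nm):
        reasons.append(f"vesicle cloud FWHM {fwhm:.0f} nm <= {min_cloud_fwhm_nm:.0f} nm")

    # marker shape from the thresholded STED channel
    elongation = 0.0
    angle_to_line = 90.0
    edge_fraction = math.nan
    thr = threshold_image(marker_image, "otsu")
    labels = measure.label(marker_image > thr, connectivity=2) if thr is not None else None
    if labels is None or labels.max() == 0:
        reasons.append("no marker object found")
    else:
        props = measure.regionprops(labels, intensity_image=marker_image)
        cx, cy = line.center_xy
        props.sort(key=lambda p: (p.centroid[0] - cy) ** 2 + (p.centroid[1] - cx) ** 2)
        p = props[0]
        minor = p.axis_minor_length
        elongation = p.axis_major_length / minor if minor > 0 else math.inf
        if not (elongation >= min_elongation):
            reasons.append(f"marker elongation {elongation:.2f} < {min_elongation}")
        # major-axis direction in xy from skimage's orientation convention
        o = p.orientation
        ux, uy = math.cos(line.angle_rad), math.sin(line.angle_rad)
        cos_between = abs(ux * math.sin(o) + uy * math.cos(o))
        angle_to_line = math.degrees(math.acos(min(cos_between, 1.0)))
        if not (angle_to_line >= 90.0 - angle_tolerance_deg):
            reasons.append(
                f"marker axis at {angle_to_line:.0f} deg to the profile, not perpendicular "
                f"within {angle_tolerance_deg:.0f} deg"
            )
        # centroid position along the profile axis, relative to cloud centre
        mx = (p.centroid[1] - cx) * ux + (p.centroid[0] - cy) * uy
        marker_pos_nm = mx * pixel_size_nm
        half_width = fwhm / 2.0
        if half_width > 0:
            edge_fraction = abs(marker_pos_nm - cloud_centre) / half_width
            lo, hi = edge_fraction_range
            if not (lo <= edge_fraction <= hi * (1.0 + 1e-6)):
                reasons.append(
                    f"marker centroid at {edge_fraction:.2f} of the cloud half-width, "
                    f"outside [{lo}, {hi}]"
                )

    return QualificationResult(
        passed=not reasons,
        cloud_fwhm_nm=fwhm,
        marker_elongation=float(elongation),
        marker_angle_to_line_deg=float(angle_to_line),
        edge_fraction=float(edge_fraction),
        reasons=reasons,
    )


def segment_marker_densities(
    image: np.ndarray,
    pixel_size_nm: float,
    min_area_um2: float = 0.04,
    max_area_um2: float = 0.4,
    threshold_method: str = "otsu",
) -> list[DensityObject]:
    """Threshold, label, and size-filter marker densities in a STED channel.

    Objects are retained when their area lies within
    [``min_area_um2``, ``max_area_um2``]; shape and orientation are not
    considered.
    """
    thr = threshold_image(image, threshold_method)
    if thr is None:
        return []
    labels = measure.label(image > thr, connectivity=2)
    out = []
    px_area_um2 = (pixel_size_nm / 1000.0) ** 2
    props = measure.regionprops(labels, intensity_image=image)
    props.sort(key=lambda p: p.centroid)
    for i, p in enumerate(props):
        area = p.area * px_area_um2
        if min_area_um2 <= area <= max_area_um2:
            out.append(
                DensityObject(
                    id=len(out),
                    centroid_rc=tuple(p.centroid),
                    area_um2=float(area),
                    mean_intensity=float(p.intensity_mean),
                )
            )
    return out


def normalize_pma_increase(
    values: np.ndarray | pd.Series,
    group_labels,
    culture_labels,
    control_label: str = "-PMA",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Express each value as % of its culture's untreated (-PMA) mean.

    Returns the per-measurement table and a per-group summary
    (mean +/- SEM of the percentages).  A culture without the control
    condition raises ``ValueError``.
    """
    df = pd.DataFrame(
        {"value": np.asarray(values, dtype=float), "group": list(group_labels), "culture": list(culture_labels)}
    )
    control_means = (
        df[df["group"] == control_label].groupby("culture")["value"].mean()
    )
    missing = sorted(set(df["culture"]) - set(control_means.index))
    if missing:
        raise ValueError(f"cultures without a {control_label} condition: {missing}")
    df["percent_of_control"] = 100.0 * df["value"] / df["culture"].map(control_means).to_numpy()
    summary = (
        df.groupby("group")["percent_of_control"]
        .agg(n="count", mean="mean", sem=lambda x: x.std(ddof=1) / math.sqrt(len(x)) if len(x) > 1 else math.nan)
        .reset_index()
    )
    return df, summary
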