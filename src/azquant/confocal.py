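"""Confocal synaptic-intensity quantification.

Local background is estimated with a circular moving-average filter
(diameter 1.4 um by default) and subtracted; the vesicle-marker channel
defines puncta as ROIs (threshold, 8-connected components, area filter);
per-ROI means of the protein channel are averaged per image and normalised
to the per-culture control mean.  Pixel-wise Pearson correlation over a
stated mask is provided for colocalization.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import measure, morphology

from azquant._segment import threshold_image

DEFAULT_BACKGROUND_DIAMETER_UM = 1.4
DEFAULT_MIN_ROI_AREA_UM2 = 0.1
DEFAULT_MAX_ROI_AREA_UM2 = 3.0


@dataclass
class ROISet:
    """Labelled puncta: label 0 = background, ROI ids start at 1."""

    label_mask: np.ndarray
    table: pd.DataFrame  # roi_id, area_um2, centroid_row, centroid_col

    @property
    def n_rois(self) -> int:
        return len(self.table)


def subtract_local_background(
    image: np.ndarray,
    pixel_size_nm: float,
    diameter_um: float = DEFAULT_BACKGROUND_DIAMETER_UM,
    method: str = "mean",
) -> np.ndarray:
    """Subtract a local-average background, clipping at zero.

    ``method="mean"`` (default) uses a circular mean filter of the stated
    diameter, following the plugin the measurement protocol names; a
    morphological ``"rolling_ball"`` alternative (same radius) is provided
    for comparison.
    """
    diameter_px = diameter_um * 1000.0 / pixel_size_nm
    if diameter_px < 2.0:
        raise ValueError(f"background diameter {diameter_um} um is under 2 px at {pixel_size_nm} nm/px")
    radius = int(round(diameter_px / 2.0))
    if method == "mean":
        footprint = morphology.disk(radius).astype(float)
        background = ndimage.correlate(image.astype(float), footprint, mode="reflect") / footprint.sum()
    elif method == "rolling_ball":
        from skimage import restoration

        background = restoration.rolling_ball(image.astype(float), radius=radius)
    else:
        raise ValueError(f"unknown background method {method!r}")
    return np.clip(image - background, 0.0, None)


def define_rois(
    vesicle_channel: np.ndarray,
    pixel_size_nm: float,
    threshold_method: str | float = "otsu",
    min_area_um2: float = DEFAULT_MIN_ROI_AREA_UM2,
    max_area_um2: float = DEFAULT_MAX_ROI_AREA_UM2,
) -> ROISet:
    """Define puncta ROIs from the (background-corrected) vesicle channel.

    8-connected components within the area bounds; touching puncta merge
    into one ROI (no watershed splitting).  Labels are renumbered in
    centroid (row, col) order for determinism.
    """
    thr = threshold_image(vesicle_channel, threshold_method)
    px_area_um2 = (pixel_size_nm / 1000.0) ** 2
    shape = vesicle_channel.shape
    if thr is None:
        return ROISet(np.zeros(shape, dtype=int), pd.DataFrame(columns=["roi_id", "area_um2", "centroid_row", "centroid_col"]))
    labels = measure.label(vesicle_channel > thr, connectivity=2)
    props = measure.regionprops(labels)
    props = [p for p in props if min_area_um2 <= p.area * px_area_um2 <= max_area_um2]
    props.sort(key=lambda p: p.centroid)
    out_mask = np.zeros(shape, dtype=int)
    rows = []
    for new_id, p in enumerate(props, start=1):
        out_mask[labels == p.label] = new_id
        rows.append(
            {
                "roi_id": new_id,
                "area_um2": p.area * px_area_um2,
                "centroid_row": p.centroid[0],
                "centroid_col": p.centroid[1],
            }
        )
    return ROISet(out_mask, pd.DataFrame(rows, columns=["roi_id", "area_um2", "centroid_row", "centroid_col"]))


def measure_roi_means(protein_channel: np.ndarray, rois: ROISet) -> tuple[pd.DataFrame, float]:
    """Per-ROI means of the protein channel and their per-image average.

    An empty ROI set yields an empty table and NaN with a warning.
    """
    if rois.n_rois == 0:
        warnings.warn("no ROIs defined; per-image mean is undefined", stacklevel=2)
        return pd.DataFrame(columns=["roi_id", "mean_intensity"]), math.nan
    ids = rois.table["roi_id"].to_numpy()
    means = ndimage.mean(protein_channel, labels=rois.label_mask, index=ids)
    table = pd.DataFrame({"roi_id": ids, "mean_intensity": means})
    return table, float(np.mean(means))


def normalize_to_control(
    values,
    group_labels,
    culture_labels,
    control_group: str = "control",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Normalise per-image values to the per-culture control mean.

    Returns the per-image table (raw and normalised) and a per-group
    summary (n, mean, SEM of the normalised values).  A culture without
    control images raises ``ValueError``.
    """
    df = pd.DataFrame(
        {"value": np.asarray(values, dtype=float), "group": list(group_labels), "culture": list(culture_labels)}
    )
    control_means = df[df["group"] == control_group].groupby("culture")["value"].mean()
    missing = sorted(set(df["culture"]) - set(control_means.index))
    if missing:
        raise ValueError(f"cultures without a {control_group} group: {missing}")
    df["normalized"] = df["value"] / df["culture"].map(control_means).to_numpy()
    summary = (
        df.groupby("group")["normalized"]
        .agg(n="count", mean="mean", sem=lambda x: x.std(ddof=1) / math.sqrt(len(x)) if len(x) > 1 else math.nan)
        .reset_index()
    )
    return df, summary


def pearson_colocalization(
    channel_a: np.ndarray,
    channel_b: np.ndarray,
    mask: np.ndarray | None = None,
) -> float:
    """Pearson correlation of pixel intensities over ``mask``.

    Plain correlation over a stated mask (no automatic thresholding).
    Zero variance in either channel makes the coefficient undefined: NaN
    is returned with a warning.
    """
    if channel_a.shape != channel_b.shape:
        raise ValueError("channels must have the same shape")
    if mask is None:
        a, b = channel_a.ravel(), channel_b.ravel()
    else:
        if mask.shape != channel_a.shape:
            raise ValueError("mask must match the channel shape")
        if not mask.any():
            raise ValueError("mask is empty")
        a, b = channel_a[mask], channel_b[mask]
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        warnings.warn("zero variance in a channel; Pearson coefficient undefined", stacklevel=2)
        return math.nan
    return float(np.corrcoef(a, b)[0, 1])
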