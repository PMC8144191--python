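"""Condensate segmentation, tracking, fusion/fission calls, and shape relaxation.

Droplet-positive cells are scored by the presence of at least one
spherical condensate larger than 1 um in (equivalent) diameter.  Tracking
links segmented objects frame to frame by greedy nearest-centroid
matching; a candidate fusion (two tracks converging on one object) is
confirmed when the product persists for at least 30 s and is at least as
large as each parent, and fission is handled symmetrically.  After a
fusion, the aspect ratio AR (longer over shorter condensate diameter)
relaxes as AR(t) = AR_inf + (AR_0 - AR_inf) * exp(-t / tau), fitted here
by unconstrained least squares.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from skimage import measure

from azquant._segment import threshold_image
from azquant.io import ImageStack

DEFAULT_MIN_DIAMETER_UM = 1.0
DEFAULT_MAX_ASPECT_RATIO = 1.5  # sphericity cutoff for "spherical" condensates
DEFAULT_MAX_LINK_DISTANCE_NM = 500.0
DEFAULT_STABILITY_S = 30.0


@dataclass
class CondensateObject:
    """One segmented condensate in one frame."""

    id: int
    frame: int
    centroid_rc: tuple[float, float]
    area_um2: float
    equivalent_diameter_um: float
    aspect_ratio: float
    mean_intensity: float


@dataclass
class Track:
    """A condensate followed over time (one object per frame)."""

    id: int
    objects: list[CondensateObject] = field(default_factory=list)

    @property
    def first_frame(self) -> int:
        return self.objects[0].frame

    @property
    def last_frame(self) -> int:
        return self.objects[-1].frame

    def object_at(self, frame: int) -> CondensateObject | None:
        for o in self.objects:
            if o.frame == frame:
                return o
        return None


@dataclass
class CandidateEvent:
    kind: str  # "fusion" | "fission"
    frame: int  # first frame of the product(s)
    parent_track_ids: list[int]
    child_track_ids: list[int]


@dataclass
class TrackingResult:
    tracks: list[Track]
    candidate_events: list[CandidateEvent]


@dataclass
class ConfirmedEvent:
    kind: str
    frame: int
    time_s: float
    parent_track_ids: list[int]
    child_track_ids: list[int]
    stable_s: float


@dataclass
class RelaxationFit:
    """AR(t) = ar_inf + (ar_0 - ar_inf) * exp(-t / tau_s)."""

    ar_0: float
    ar_inf: float
    tau_s: float
    rss: float
    n_points: int
    converged: bool
    degenerate: bool = False
    sub_unity_asymptote: bool = False  # flag: fit is unconstrained


def segment_condensates(
    frame: np.ndarray,
    pixel_size_nm: float,
    min_diameter_um: float = DEFAULT_MIN_DIAMETER_UM,
    threshold_method: str | float = "otsu",
) -> list[CondensateObject]:
    """Threshold a single-channel frame and keep objects >= ``min_diameter_um``.

    The diameter filter uses the equivalent diameter from area,
    2*sqrt(A/pi).  Objects are ordered deterministically by centroid
    (row, col).  An all-zero or constant frame yields an empty list.
    """
    if frame.ndim != 2:
        raise ValueError("segment_condensates expects a single-channel 2D frame")
    if not (pixel_size_nm > 0):
        raise ValueError("pixel_size_nm calibration is required")
    thr = threshold_image(frame, threshold_method)
    if thr is None:
        return []
    labels = measure.label(frame > thr, connectivity=2)
    if labels.max() == 0:
        return []
    px_area_um2 = (pixel_size_nm / 1000.0) ** 2
    props = measure.regionprops(labels, intensity_image=frame)
    props.sort(key=lambda p: p.centroid)
    out: list[CondensateObject] = []
    for p in props:
        area_um2 = p.area * px_area_um2
        eq_diam = 2.0 * math.sqrt(area_um2 / math.pi)
        if eq_diam < min_diameter_um:
            continue
        minor = p.axis_minor_length
        major = p.axis_major_length
        if minor > 0:
            ar = major / minor
        else:
            ar = 1.0 if p.area == 1 else math.inf
        out.append(
            CondensateObject(
                id=len(out),
                frame=0,
                centroid_rc=tuple(p.centroid),
                area_um2=float(area_um2),
                equivalent_diameter_um=float(eq_diam),
                aspect_ratio=float(max(ar, 1.0)),
                mean_intensity=float(p.intensity_mean),
            )
        )
    return out


def classify_cell_droplet_positive(
    cell_image: np.ndarray,
    pixel_size_nm: float,
    min_diameter_um: float = DEFAULT_MIN_DIAMETER_UM,
    max_aspect_ratio: float = DEFAULT_MAX_ASPECT_RATIO,
    threshold_method: str | float = "otsu",
) -> bool:
    """True iff the cell contains >= 1 spherical condensate above the size cutoff."""
    objects = segment_condensates(cell_image, pixel_size_nm, min_diameter_um, threshold_method)
    return any(o.aspect_ratio <= max_aspect_ratio for o in objects)


def count_and_size_condensates(
    frames: np.ndarray | list[np.ndarray],
    pixel_size_nm: float,
    min_diameter_um: float = DEFAULT_MIN_DIAMETER_UM,
    threshold_method: str | float = "otsu",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-image condensate counts and a per-object size table."""
    counts = []
    sizes = []
    for i, frame in enumerate(frames):
        objs = segment_condensates(frame, pixel_size_nm, min_diameter_um, threshold_method)
        counts.append({"image": i, "n_condensates": len(objs)})
        for o in objs:
            sizes.append(
                {
                    "image": i,
                    "object_id": o.id,
                    "area_um2": o.area_um2,
                    "equivalent_diameter_um": o.equivalent_diameter_um,
                    "aspect_ratio": o.aspect_ratio,
                    "mean_intensity": o.mean_intensity,
                }
            )
    return pd.DataFrame(counts), pd.DataFrame(sizes)


def _segment_stack(stack: ImageStack, min_diameter_um, threshold_method) -> list[list[CondensateObject]]:
    per_frame = []
    for f in range(stack.n_frames):
        objs = segment_condensates(stack.frame(f), stack.pixel_size_nm, min_diameter_um, threshold_method)
        for o in objs:
            o.frame = f
        per_frame.append(objs)
    return per_frame


def track_condensates(
    stack_or_objects: ImageStack | list[list[CondensateObject]],
    pixel_size_nm: float | None = None,
    max_link_distance_nm: float = DEFAULT_MAX_LINK_DISTANCE_NM,
    min_diameter_um: float = DEFAULT_MIN_DIAMETER_UM,
    threshold_method: str | float = "otsu",
) -> TrackingResult:
    """Greedy nearest-centroid frame-to-frame tracking with event candidates.

    Two tracks converging on one next-frame object end there and the
    product starts a new track (candidate fusion); a continuing track that
    also spawns an extra nearby object is ended and both offspring start
    new tracks (candidate fission).  Equal-distance ties break toward the
    lower object id.
    """
    if isinstance(stack_or_objects, ImageStack):
        pixel_size_nm = stack_or_objects.pixel_size_nm
        per_frame = _segment_stack(stack_or_objects, min_diameter_um, threshold_method)
    else:
        if pixel_size_nm is None:
            raise ValueError("pixel_size_nm is required when passing pre-segmented objects")
        per_frame = stack_or_objects

    max_link_px = max_link_distance_nm / pixel_size_nm
    tracks: list[Track] = []
    candidates: list[CandidateEvent] = []
    # track id currently owning each object of the previous frame
    prev_owner: dict[int, int] = {}

    for f, objs in enumerate(per_frame):
        if f == 0:
            for o in objs:
                tracks.append(Track(id=len(tracks), objects=[o]))
            prev_owner = {o.id: t.id for o, t in zip(objs, tracks)}
            continue

        prev_objs = per_frame[f - 1]
        pairs = []
        for p in prev_objs:
            for c in objs:
                d = math.hypot(p.centroid_rc[0] - c.centroid_rc[0], p.centroid_rc[1] - c.centroid_rc[1])
                if d <= max_link_px:
                    pairs.append((d, p.id, c.id))
        pairs.sort()
        link_pc: dict[int, int] = {}
        link_cp: dict[int, int] = {}
        for d, pid, cid in pairs:
            if pid in link_pc or cid in link_cp:
                continue
            link_pc[pid] = cid
            link_cp[cid] = pid

        # nearest in-range candidate per unmatched object (for event calls)
        nearest_c_for_p: dict[int, int] = {}
        nearest_p_for_c: dict[int, int] = {}
        for d, pid, cid in pairs:
            nearest_c_for_p.setdefault(pid, cid)
            nearest_p_for_c.setdefault(cid, pid)

        fusion_children: dict[int, list[int]] = {}  # cid -> prev ids converging on it
        for p in prev_objs:
            if p.id in link_pc:
                continue
            cid = nearest_c_for_p.get(p.id)
            if cid is not None and cid in link_cp:
                fusion_children.setdefault(cid, []).append(p.id)

        fission_parents: dict[int, list[int]] = {}  # pid -> new-object ids it spawned
        for c in objs:
            if c.id in link_cp:
                continue
            pid = nearest_p_for_c.get(c.id)
            if pid is not None and pid in link_pc and link_pc[pid] not in fusion_children:
                fission_parents.setdefault(pid, []).append(c.id)

        new_owner: dict[int, int] = {}
        consumed_links: set[int] = set()

        for cid, extra_parents in fusion_children.items():
            linked_pid = link_cp[cid]
            child = Track(id=len(tracks), objects=[next(o for o in objs if o.id == cid)])
            tracks.append(child)
            new_owner[cid] = child.id
            consumed_links.add(cid)
            parent_tids = sorted(prev_owner[pid] for pid in [linked_pid, *extra_parents])
            candidates.append(
                CandidateEvent(kind="fusion", frame=f, parent_track_ids=parent_tids, child_track_ids=[child.id])
            )

        for pid, extra_children in fission_parents.items():
            linked_cid = link_pc[pid]
            child_tids = []
            for cid in sorted([linked_cid, *extra_children]):
                child = Track(id=len(tracks), objects=[next(o for o in objs if o.id == cid)])
                tracks.append(child)
                new_owner[cid] = child.id
                consumed_links.add(cid)
                child_tids.append(child.id)
            candidates.append(
                CandidateEvent(kind="fission", frame=f, parent_track_ids=[prev_owner[pid]], child_track_ids=child_tids)
            )

        for c in objs:
            if c.id in new_owner:
                continue
            pid = link_cp.get(c.id)
            if pid is not None and c.id not in consumed_links:
                tid = prev_owner[pid]
                tracks[tid].objects.append(c)
                new_owner[c.id] = tid
            else:
                t = Track(id=len(tracks), objects=[c])
                tracks.append(t)
                new_owner[c.id] = t.id

        prev_owner = new_owner

    return TrackingResult(tracks=tracks, candidate_events=candidates)


def detect_fusion_fission(
    result: TrackingResult,
    frame_interval_s: float,
    stability_s: float = DEFAULT_STABILITY_S,
) -> list[ConfirmedEvent]:
    """Confirm candidate events against the stability and size criteria.

    A fusion is confirmed when the product track persists at least
    ``stability_s`` and the product is at least as large as each parent;
    fission symmetrically requires both offspring to persist and the
    parent to be at least as large as each offspring.
    """
    tracks = {t.id: t for t in result.tracks}
    confirmed = []
    for ev in result.candidate_events:
        parents = [tracks[i] for i in ev.parent_track_ids]
        children = [tracks[i] for i in ev.child_track_ids]
        stable_s = min((c.last_frame - c.first_frame) * frame_interval_s for c in children)
        if stable_s < stability_s:
            continue
        parent_areas = [p.objects[-1].area_um2 for p in parents]
        child_areas = [c.objects[0].area_um2 for c in children]
        if ev.kind == "fusion":
            if not all(child_areas[0] >= a for a in parent_areas):
                continue
        else:
            if not all(parent_areas[0] >= a for a in child_areas):
                continue
        confirmed.append(
            ConfirmedEvent(
                kind=ev.kind,
                frame=ev.frame,
                time_s=ev.frame * frame_interval_s,
                parent_track_ids=ev.parent_track_ids,
                child_track_ids=ev.child_track_ids,
                stable_s=float(stable_s),
            )
        )
    return confirmed


def fit_relaxation(times_s: np.ndarray, ar_values: np.ndarray) -> RelaxationFit:
    """Unweighted least-squares fit of the exponential aspect-ratio decay.

    Time is measured from the first sample (fusion at t = 0).
    Initialisation: ar_0 = first value, ar_inf = last value,
    tau = span / 3.  The asymptote is unconstrained (empirical fits can
    fall slightly below 1) but a sub-unity result is flagged.
    """
    t = np.asarray(times_s, dtype=float)
    ar = np.asarray(ar_values, dtype=float)
    if t.size < 4:
        raise ValueError("need at least 4 points to fit the relaxation")
    if np.any(np.diff(t) <= 0):
        raise ValueError("times must be strictly increasing")
    t = t - t[0]

    if np.ptp(ar) == 0:
        v = float(ar[0])
        return RelaxationFit(
            ar_0=v, ar_inf=v, tau_s=math.nan, rss=0.0, n_points=t.size, converged=True,
            degenerate=True, sub_unity_asymptote=v < 1.0,
        )

    def model(t, ar_0, ar_inf, tau):
        return ar_inf + (ar_0 - ar_inf) * np.exp(-t / tau)

    span = t[-1] - t[0]
    p0 = (float(ar[0]), float(ar[-1]), span / 3.0)
    try:
        popt, _ = curve_fit(
            model, t, ar, p0=p0,
            bounds=([-np.inf, -np.inf, 1e-9], [np.inf, np.inf, np.inf]),
            maxfev=20000,
        )
    except RuntimeError:
        return RelaxationFit(
            ar_0=math.nan, ar_inf=math.nan, tau_s=math.nan, rss=math.inf,
            n_points=t.size, converged=False,
        )
    rss = float(np.sum((model(t, *popt) - ar) ** 2))
    return RelaxationFit(
        ar_0=float(popt[0]),
        ar_inf=float(popt[1]),
        tau_s=float(popt[2]),
        rss=rss,
        n_points=t.size,
        converged=True,
        sub_unity_asymptote=popt[1] < 1.0,
    )
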