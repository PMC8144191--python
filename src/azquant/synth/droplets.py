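"""Time-lapse movies of liquid-phase droplets with fusion ground truth.

Droplets are rendered as filled disks; after a fusion event the product is
an ellipse of conserved area whose aspect ratio relaxes exponentially,
AR(t) = AR_inf + (AR_0 - AR_inf) * exp(-t / tau), with AR_0 set by the
touching-parent geometry and the long axis along the pre-fusion axis.
Sub-resolution detail is not modelled; the geometry is rasterised at pixel
centres and blurred with the scene PSF.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from azquant.io import ImageStack
from azquant.synth.scene import GroundTruth, SceneSpec, apply_noise, apply_psf


@dataclass(frozen=True)
class DropletSpec:
    """A spherical condensate planted in the scene.

    ``center_xy`` is the (col, row) pixel position at ``birth_frame``;
    droplets may drift linearly.  ``death_frame`` is inclusive; ``None``
    means the droplet lives to the end of the movie (or until consumed by
    a fusion event).
    """

    center_xy: tuple[float, float]
    radius_nm: float
    intensity: float = 100.0
    birth_frame: int = 0
    death_frame: int | None = None
    velocity_px_per_frame: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if not (self.radius_nm > 0):
            raise ValueError("radius_nm must be > 0")
        if self.intensity < 0:
            raise ValueError("intensity must be >= 0")
        if self.death_frame is not None and self.birth_frame > self.death_frame:
            raise ValueError("birth_frame must be <= death_frame")

    def position(self, frame: int) -> tuple[float, float]:
        dt = frame - self.birth_frame
        return (
            self.center_xy[0] + self.velocity_px_per_frame[0] * dt,
            self.center_xy[1] + self.velocity_px_per_frame[1] * dt,
        )


@dataclass(frozen=True)
class FusionEventSpec:
    """Two parent droplets coalesce into one relaxing ellipse.

    Area is conserved (product area = sum of parent areas).  The initial
    aspect ratio AR_0 = (r1 + r2) / max(r1, r2) follows from the touching
    disks' bounding geometry.  ``child_death_frame`` allows planting
    products that dissolve early (sub-threshold stability).
    """

    parent_ids: tuple[int, int]
    fusion_frame: int
    tau_s: float = 7.41
    ar_inf: float = 1.0
    child_death_frame: int | None = None

    def __post_init__(self) -> None:
        if len(self.parent_ids) != 2 or self.parent_ids[0] == self.parent_ids[1]:
            raise ValueError("parent_ids must be two distinct droplet indices")
        if not (self.tau_s > 0):
            raise ValueError("tau_s must be > 0")


def _render_ellipse(
    image: np.ndarray,
    cx: float,
    cy: float,
    a_px: float,
    b_px: float,
    theta: float,
    intensity: float,
) -> None:
    """Add ``intensity`` inside the ellipse (semi-axes a >= b, angle theta)."""
    rows, cols = image.shape
    r = max(a_px, b_px) + 1.5
    r0, r1 = max(0, int(cy - r)), min(rows, int(cy + r) + 2)
    c0, c1 = max(0, int(cx - r)), min(cols, int(cx + r) + 2)
    if r0 >= r1 or c0 >= c1:
        return
    yy, xx = np.mgrid[r0:r1, c0:c1]
    dx = xx - cx
    dy = yy - cy
    ct, st = math.cos(theta), math.sin(theta)
    u = (dx * ct + dy * st) / a_px
    v = (-dx * st + dy * ct) / b_px
    image[r0:r1, c0:c1] += intensity * ((u * u + v * v) <= 1.0)


def render_droplet_movie(
    scene: SceneSpec,
    droplets: list[DropletSpec],
    events: list[FusionEventSpec] | tuple = (),
    n_frames: int = 1,
    annotations: list[dict] | tuple = (),
) -> tuple[ImageStack, GroundTruth]:
    """Render a single-channel droplet movie and its analytic ground truth.

    Returns the image stack and a :class:`GroundTruth` whose ``objects``
    table holds one row per rendered object per frame (analytic centroid,
    area and aspect ratio) and whose ``events`` list records each planted
    fusion (plus any caller ``annotations``, e.g. planted fissions).
    """
    px = scene.pixel_size_nm
    truth = GroundTruth()
    margin = 3.0 * scene.psf_sigma_px

    # Resolve fusion events: parents die the frame before fusion.
    parent_death: dict[int, int] = {}
    children = []  # (event, child record)
    for k, ev in enumerate(events):
        i, j = ev.parent_ids
        for p in (i, j):
            if p < 0 or p >= len(droplets):
                raise ValueError(f"fusion event references unknown droplet {p}")
        for p in (i, j):
            parent_death[p] = min(parent_death.get(p, ev.fusion_frame - 1), ev.fusion_frame - 1)
        di, dj = droplets[i], droplets[j]
        xi, yi = di.position(ev.fusion_frame - 1)
        xj, yj = dj.position(ev.fusion_frame - 1)
        area_nm2 = math.pi * (di.radius_nm**2 + dj.radius_nm**2)
        wi = di.radius_nm**2 / (di.radius_nm**2 + dj.radius_nm**2)
        ar_0 = (di.radius_nm + dj.radius_nm) / max(di.radius_nm, dj.radius_nm)
        children.append(
            {
                "event_index": k,
                "id": len(droplets) + k,
                "center_xy": (wi * xi + (1 - wi) * xj, wi * yi + (1 - wi) * yj),
                "area_nm2": area_nm2,
                "theta": math.atan2(yj - yi, xj - xi),
                "ar_0": ar_0,
                "ar_inf": ev.ar_inf,
                "tau_s": ev.tau_s,
                "fusion_frame": ev.fusion_frame,
                "death_frame": ev.child_death_frame,
                "intensity": (di.intensity + dj.intensity) / 2.0,
            }
        )
        truth.events.append(
            {
                "kind": "fusion",
                "frame": ev.fusion_frame,
                "time_s": ev.fusion_frame * scene.frame_interval_s,
                "parent_ids": list(ev.parent_ids),
                "child_id": len(droplets) + k,
                "tau_s": ev.tau_s,
                "ar_0": ar_0,
                "ar_inf": ev.ar_inf,
                "area_nm2": area_nm2,
            }
        )
    truth.events.extend(dict(a) for a in annotations)

    fusing_pairs = {frozenset(ev.parent_ids) for ev in events}
    frames = np.zeros((n_frames, *scene.shape), dtype=float)
    rows_out = []
    warned: set = set()

    for f in range(n_frames):
        active = []  # (id, cx, cy, a_px, b_px, theta, intensity, radius_px or None)
        for idx, d in enumerate(droplets):
            death = parent_death.get(idx, d.death_frame)
            if d.death_frame is not None:
                death = min(death, d.death_frame) if death is not None else d.death_frame
            if f < d.birth_frame or (death is not None and f > death):
                continue
            cx, cy = d.position(f)
            r_px = d.radius_nm / px
            active.append((idx, cx, cy, r_px, r_px, 0.0, d.intensity))
        for ch in children:
            death = ch["death_frame"]
            if f < ch["fusion_frame"] or (death is not None and f > death):
                continue
            t = (f - ch["fusion_frame"]) * scene.frame_interval_s
            ar = ch["ar_inf"] + (ch["ar_0"] - ch["ar_inf"]) * math.exp(-t / ch["tau_s"])
            ar = max(ar, 1.0)
            b_nm = math.sqrt(ch["area_nm2"] / (math.pi * ar))
            a_nm = ar * b_nm
            active.append(
                (ch["id"], ch["center_xy"][0], ch["center_xy"][1], a_nm / px, b_nm / px, ch["theta"], ch["intensity"])
            )

        for oid, cx, cy, a_px, b_px, theta, inten in active:
            reach = a_px + margin
            if cx - reach < 0 or cy - reach < 0 or cx + reach > scene.shape[1] - 1 or cy + reach > scene.shape[0] - 1:
                raise ValueError(
                    f"droplet/product {oid} at frame {f} does not fit within the image after blur margin"
                )
            _render_ellipse(frames[f], cx, cy, a_px, b_px, theta, inten)
            area_um2 = math.pi * a_px * b_px * (px / 1000.0) ** 2
            rows_out.append(
                {
                    "frame": f,
                    "object_id": oid,
                    "cx_px": cx,
                    "cy_px": cy,
                    "area_um2": area_um2,
                    "aspect_ratio": a_px / b_px,
                    "intensity": inten,
                }
            )

        # warn (once per pair) about overlapping non-fusing droplets
        for i in range(len(active)):
            for j in range(i + 1, len(active)):
                ai, aj = active[i], active[j]
                pair = frozenset((ai[0], aj[0]))
                if pair in fusing_pairs or pair in warned:
                    continue
                dist = math.hypot(ai[1] - aj[1], ai[2] - aj[2])
                if dist < ai[3] + aj[3]:
                    warned.add(pair)
                    truth.warnings.append(
                        f"objects {sorted(pair)} overlap at frame {f} without a fusion event"
                    )

    rng = scene.rng()
    for f in range(n_frames):
        frames[f] = apply_noise(apply_psf(frames[f], scene) + scene.background_level, scene, rng)

    truth.objects = pd.DataFrame(rows_out)
    truth.params = {
        "pixel_size_nm": px,
        "frame_interval_s": scene.frame_interval_s,
        "n_frames": n_frames,
        "seed": scene.seed,
    }
    stack = ImageStack(frames[..., None], pixel_size_nm=px, frame_interval_s=scene.frame_interval_s)
    return stack, truth


def random_droplet_field(
    scene: SceneSpec,
    n_droplets: int,
    rng: np.random.Generator,
    radius_range_nm: tuple[float, float] = (600.0, 1500.0),
    intensity: float = 100.0,
    max_tries: int = 2000,
) -> list[DropletSpec]:
    """Place non-overlapping static droplets uniformly in the usable area."""
    placed: list[DropletSpec] = []
    rows, cols = scene.shape
    margin_px = radius_range_nm[1] / scene.pixel_size_nm + 3.0 * scene.psf_sigma_px + 2.0
    for _ in range(n_droplets):
        for attempt in range(max_tries):
            r_nm = rng.uniform(*radius_range_nm)
            cx = rng.uniform(margin_px, cols - 1 - margin_px)
            cy = rng.uniform(margin_px, rows - 1 - margin_px)
            r_px = r_nm / scene.pixel_size_nm
            ok = all(
                math.hypot(cx - d.center_xy[0], cy - d.center_xy[1])
                > r_px + d.radius_nm / scene.pixel_size_nm + 2.0
                for d in placed
            )
            if ok:
                placed.append(DropletSpec(center_xy=(cx, cy), radius_nm=r_nm, intensity=intensity))
                break
        else:
            raise RuntimeError("could not place droplets without overlap; reduce density")
    return placed
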