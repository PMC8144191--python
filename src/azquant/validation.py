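"""Closed-loop validation studies: generator -> analysis -> truth comparison.

Each function renders synthetic data with known ground truth, runs the
corresponding analysis stage, and returns summary error metrics.  These
studies back both the test suite and the reproducibility script; problem
sizes are chosen to finish in seconds on one CPU.
"""

from __future__ import annotations

import math
from typing import Callable

import numpy as np

from azquant import condensates as cond
from azquant import confocal as conf
from azquant import frap as frap_mod
from azquant import stats as stats_mod
from azquant import sted as sted_mod
from azquant.synth import (
    DropletSpec,
    FRAPTraceSpec,
    FusionEventSpec,
    SceneSpec,
    SideViewSpec,
    render_droplet_movie,
    render_frap_trace,
    render_sideview_image,
    simulate_confocal_cohort,
    simulate_sideview_profile,
)
from azquant.synth.sideview import true_profile_line


def relaxation_recovery_study(
    seed: int = 0,
    tau_values=(3.0, 5.0, 7.41, 10.0, 15.0),
    ar_inf_values=(0.93, 1.0, 1.1),
    amplitude: float = 1.48,
    noise_sd: float = 0.05,
    n_noise_seeds: int = 50,
) -> dict:
    """Recover (tau, AR_inf) from exponential aspect-ratio decays.

    Noiseless curves across the parameter grid (sampled 0-40 s at 1 Hz,
    the regime of the published coalescence fit), plus a Monte-Carlo run
    with Gaussian noise on the published-curve parameters.
    """
    t = np.arange(0.0, 41.0)
    tau_errs, inf_errs = [], []
    for tau in tau_values:
        for ar_inf in ar_inf_values:
            ar = ar_inf + amplitude * np.exp(-t / tau)
            fit = cond.fit_relaxation(t, ar)
            tau_errs.append(abs(fit.tau_s - tau) / tau)
            inf_errs.append(abs(fit.ar_inf - ar_inf) / abs(ar_inf))
    rng = np.random.default_rng(seed)
    noisy_errs = []
    for _ in range(n_noise_seeds):
        ar = 0.93 + 1.48 * np.exp(-t / 7.41) + rng.normal(0.0, noise_sd, t.size)
        fit = cond.fit_relaxation(t, ar)
        noisy_errs.append(abs(fit.tau_s - 7.41) / 7.41)
    return {
        "n_noiseless_fits": len(tau_errs),
        "max_tau_rel_error_noiseless": float(max(tau_errs)),
        "max_ar_inf_rel_error_noiseless": float(max(inf_errs)),
        "median_tau_rel_error_noisy": float(np.median(noisy_errs)),
    }


def frap_consistency_study(
    seed: int = 0,
    k_values=(0.02, 0.05, 0.1, 0.2),
    mobile_fractions=(0.2, 0.4, 0.6, 0.8, 1.0),
    frame_interval_s: float = 1.0,
) -> dict:
    """Half-time, mobile-fraction, and double-bleach closure on synthetic traces.

    Trace lengths scale with 1/k so each segment reaches its plateau
    (k * T >= 6) before the next event.
    """
    thalf_errs, mobile_errs, second_fracs = [], [], []
    for k in k_values:
        seg_frames = int(math.ceil(6.0 / (k * frame_interval_s)))
        for mf in mobile_fractions:
            spec = FRAPTraceSpec(
                bleach_frames=(5, 5 + seg_frames),
                mobile_fraction=mf,
                recovery_rate_per_s=k,
                bleach_floor_fraction=0.05,
                noise_sd=0.0,
            )
            trace, truth = render_frap_trace(spec, n_frames=5 + 2 * seg_frames, frame_interval_s=frame_interval_s)
            first, second = frap_mod.analyze_frap_trace(trace)
            thalf_errs.append(abs(first.t_half_s - truth.params["t_half_s"]))
            mobile_errs.append(abs(first.mobile_fraction - mf))
            second_fracs.append(second.max_recovered_fraction)
    return {
        "n_traces": len(thalf_errs),
        "max_t_half_error_s": float(max(thalf_errs)),
        "frame_interval_s": frame_interval_s,
        "max_mobile_fraction_error": float(max(mobile_errs)),
        "min_second_bleach_recovered_fraction": float(min(second_fracs)),
    }


def sted_peak_study(
    seed: int = 0,
    n_synapses: int = 100,
    n_decoy_cases: int = 1000,
    pixel_size_nm: float = 22.5,
) -> dict:
    """Peak localization on rendered side views and the window guarantee.

    ``n_synapses`` full image renders with protein offsets uniform in
    +/-90 nm measure the localization error; ``n_decoy_cases`` randomized
    analytic profiles with brighter out-of-window decoys count window
    violations.
    """
    rng = np.random.default_rng(seed)
    errors = []
    for _ in range(n_synapses):
        offset = float(rng.uniform(-90.0, 90.0))
        scene = SceneSpec(
            shape=(96, 96), pixel_size_nm=pixel_size_nm, psf_sigma_nm=30.0, seed=int(rng.integers(0, 2**31))
        )
        spec = SideViewSpec(protein_offset_nm=offset, axis_angle_rad=float(rng.uniform(0.0, math.pi)))
        stack, truth = render_sideview_image(scene, spec)
        profile = sted_mod.extract_profile(stack, true_profile_line(scene, spec))
        peaks = sted_mod.measure_peaks(profile, 1, 2)
        measured = peaks.protein_peak_pos_nm - peaks.marker_peak_pos_nm
        errors.append(abs(measured - offset))

    violations = 0
    for _ in range(n_decoy_cases):
        spec = SideViewSpec(
            protein_offset_nm=float(rng.uniform(-90.0, 90.0)),
            protein_peak_intensity=float(rng.uniform(80.0, 200.0)),
            decoy_peaks=(
                (float(rng.choice([-1, 1]) * rng.uniform(130.0, 420.0)), float(rng.uniform(250.0, 900.0))),
            ),
        )
        profile, _ = simulate_sideview_profile(spec, pixel_size_nm=pixel_size_nm)
        peaks = sted_mod.measure_peaks(profile, 1, 2)
        if peaks.peak_distance_nm > 100.0 + 1e-9:
            violations += 1
    return {
        "n_synapses": n_synapses,
        "mean_abs_localization_error_nm": float(np.mean(errors)),
        "pixel_size_nm": pixel_size_nm,
        "n_decoy_cases": n_decoy_cases,
        "window_violations": violations,
    }


def segmentation_exactness_study(
    seed: int = 0,
    n_condensate_scenes: int = 250,
    n_density_scenes: int = 250,
) -> dict:
    """Exact object counting on noiseless scenes away from the cutoffs.

    Condensate scenes mix sub- and supra-cutoff disks (>= 2 px clear of
    the 1-um diameter cutoff); density scenes mix rectangles >= 2 px clear
    of the 0.04-0.4 um^2 area filter at 22.5 nm/px.
    """
    rng = np.random.default_rng(seed)
    count_mismatches = 0
    for _ in range(n_condensate_scenes):
        scene = SceneSpec(shape=(128, 128), pixel_size_nm=100.0, psf_sigma_nm=0.0, seed=0)
        n_obj = int(rng.integers(0, 7))
        droplets, expected = [], 0
        placed: list[tuple[float, float, float]] = []
        for _ in range(n_obj):
            above = bool(rng.random() < 0.6)
            r_nm = float(rng.uniform(600.0, 1100.0)) if above else float(rng.uniform(250.0, 400.0))
            for _ in range(200):
                cx = rng.uniform(14.0, 113.0)
                cy = rng.uniform(14.0, 113.0)
                if all(math.hypot(cx - x, cy - y) > (r_nm + r2) / 100.0 + 2.0 for x, y, r2 in placed):
                    placed.append((cx, cy, r_nm))
                    droplets.append(DropletSpec(center_xy=(cx, cy), radius_nm=r_nm))
                    expected += above
                    break
        if droplets:
            stack, _ = render_droplet_movie(scene, droplets, n_frames=1)
            frame = stack.frame(0)
        else:
            frame = np.zeros(scene.shape)
        objs = cond.segment_condensates(frame, 100.0, min_diameter_um=1.0)
        count_mismatches += len(objs) != expected

    px = 22.5
    px_area = (px / 1000.0) ** 2  # 0.00050625 um^2
    density_mismatches = 0
    for _ in range(n_density_scenes):
        img = np.zeros((160, 160))
        n_obj = int(rng.integers(0, 7))
        expected = 0
        boxes: list[tuple[int, int, int, int]] = []
        for _ in range(n_obj):
            cls = rng.integers(0, 3)  # below, inside, above the area band
            if cls == 0:
                area_px = int(rng.integers(20, 70))  # <= 77 px (0.04 um^2 - 2 px)
            elif cls == 1:
                area_px = int(rng.integers(100, 700))  # inside [81, 788]
            else:
                area_px = int(rng.integers(800, 1100))  # >= 792 px
            w = int(rng.integers(max(3, int(math.sqrt(area_px) / 2)), int(2 * math.sqrt(area_px))))
            h = max(1, area_px // w)
            area_px = w * h
            in_band = 79 + 2 <= area_px <= 790 - 2
            out_band = area_px <= 79 - 2 or area_px >= 790 + 2
            if not (in_band or out_band):
                continue  # too close to a cutoff to count unambiguously
            for _ in range(200):
                r0 = int(rng.integers(2, 158 - h))
                c0 = int(rng.integers(2, 158 - w))
                if all(
                    r0 + h + 2 < rr or rr2 + 2 < r0 or c0 + w + 2 < cc or cc2 + 2 < c0
                    for rr, cc, rr2, cc2 in boxes
                ):
                    boxes.append((r0, c0, r0 + h, c0 + w))
                    img[r0 : r0 + h, c0 : c0 + w] = 100.0
                    expected += in_band
                    break
        objs = sted_mod.segment_marker_densities(img, px, 0.04, 0.4)
        density_mismatches += len(objs) != expected

    return {
        "n_condensate_scenes": n_condensate_scenes,
        "condensate_count_mismatches": count_mismatches,
        "n_density_scenes": n_density_scenes,
        "density_count_mismatches": density_mismatches,
    }


def fusion_fission_recall_study(seed: int = 0, n_movies: int = 100) -> dict:
    """Event calls on movies with planted fusions/fissions.

    One third of the movies carry a stable fusion (product alive >= 30 s),
    one third a sub-threshold fusion (product dies early), one third a
    fission; each must yield exactly the planted confirmed events with the
    event frame within one frame of truth.
    """
    rng = np.random.default_rng(seed)
    wrong_calls = 0
    max_frame_err = 0
    for m in range(n_movies):
        kind = ("stable_fusion", "short_fusion", "fission")[m % 3]
        scene = SceneSpec(shape=(96, 96), pixel_size_nm=100.0, psf_sigma_nm=0.0, frame_interval_s=1.0, seed=0)
        event_frame = int(rng.integers(5, 12))
        cy = float(rng.uniform(40.0, 56.0))
        if kind == "fission":
            droplets = [
                DropletSpec(center_xy=(48, cy), radius_nm=900, death_frame=event_frame - 1),
                DropletSpec(center_xy=(40, cy), radius_nm=620, birth_frame=event_frame),
                DropletSpec(center_xy=(56, cy), radius_nm=630, birth_frame=event_frame),
            ]
            events = []
            expected = [("fission", event_frame)]
        else:
            r = float(rng.uniform(600.0, 750.0))
            gap = 2.0
            x0 = 46.0 - r / 100.0 - gap / 2.0
            x1 = 50.0 + r / 100.0 + gap / 2.0
            droplets = [
                DropletSpec(center_xy=(x0, cy), radius_nm=r),
                DropletSpec(center_xy=(x1, cy), radius_nm=r),
            ]
            death = None if kind == "stable_fusion" else event_frame + int(rng.integers(5, 25))
            events = [FusionEventSpec(parent_ids=(0, 1), fusion_frame=event_frame, tau_s=7.41, child_death_frame=death)]
            expected = [("fusion", event_frame)] if kind == "stable_fusion" else []
        n_frames = event_frame + 45
        stack, _ = render_droplet_movie(scene, droplets, events, n_frames=n_frames)
        # the product centroid sits ~ (parent radius + half gap) from each
        # parent, so the link radius must cover that reach
        tracking = cond.track_condensates(stack, max_link_distance_nm=1200.0)
        confirmed = cond.detect_fusion_fission(tracking, 1.0, stability_s=30.0)
        found = sorted((c.kind, c.frame) for c in confirmed)
        if len(found) != len(expected) or any(k != ek for (k, _), (ek, _) in zip(found, expected)):
            wrong_calls += 1
        else:
            for (k, f), (ek, ef) in zip(found, expected):
                max_frame_err = max(max_frame_err, abs(f - ef))
    return {
        "n_movies": n_movies,
        "wrong_event_calls": wrong_calls,
        "max_event_frame_error": max_frame_err,
    }


def oracle_equivalence_study(
    smooth_oracle: Callable,
    holm_oracle: Callable,
    component_count_oracle: Callable,
    seed: int = 0,
    n_cases: int = 1000,
) -> dict:
    """Exact agreement of core primitives with independent brute-force oracles."""
    rng = np.random.default_rng(seed)
    smooth_dev = 0.0
    for _ in range(n_cases):
        v = rng.normal(0.0, 50.0, int(rng.integers(5, 60)))
        smooth_dev = max(smooth_dev, float(np.max(np.abs(sted_mod.smooth_profile(v, 5) - smooth_oracle(v, 5)))))
    holm_dev = 0.0
    for _ in range(n_cases):
        p = rng.random(int(rng.integers(1, 12)))
        holm_dev = max(holm_dev, float(np.max(np.abs(stats_mod.holm_adjust(p) - holm_oracle(p)))))
    roi_mismatches = 0
    for _ in range(n_cases):
        mask = rng.random((24, 24)) < 0.25
        rois = conf.define_rois(mask.astype(float), 100.0, threshold_method=0.5, min_area_um2=0.0, max_area_um2=np.inf)
        roi_mismatches += rois.n_rois != component_count_oracle(mask)
    return {
        "n_cases_each": n_cases,
        "smoothing_max_abs_deviation": smooth_dev,
        "holm_max_abs_deviation": holm_dev,
        "roi_count_mismatches": roi_mismatches,
    }


def cohort_effect_study(
    seed: int = 0,
    true_ratio: float = 0.65,
    n_cultures: int = 3,
    images_per_group: int = 5,
    n_null_reps: int = 2000,
    n_per_group_null: int = 15,
    alpha: float = 0.05,
) -> dict:
    """End-to-end effect recovery plus pipeline type-I error under a null.

    A noiseless cohort planted with ``true_ratio`` runs through background
    subtraction, ROI definition, intensity measurement, per-culture
    normalization, and the assumption-gated test; the null study feeds
    Gaussian same-distribution groups through the same select-and-test
    pipeline and reports the fraction rejected at ``alpha``.
    """
    scene = SceneSpec(shape=(160, 160), pixel_size_nm=100.0, psf_sigma_nm=0.0, seed=seed)
    records, _ = simulate_confocal_cohort(
        scene, {"control": 1.0, "KO": true_ratio}, n_cultures=n_cultures,
        images_per_group=images_per_group, seed=seed,
    )
    values, groups, cultures = [], [], []
    for rec in records:
        img = rec["stack"]
        marker = conf.subtract_local_background(img.frame(0, 0), img.pixel_size_nm)
        protein = conf.subtract_local_background(img.frame(0, 1), img.pixel_size_nm)
        rois = conf.define_rois(marker, img.pixel_size_nm)
        _, image_mean = conf.measure_roi_means(protein, rois)
        values.append(image_mean)
        groups.append(rec["group"])
        cultures.append(rec["culture"])
    table, summary = conf.normalize_to_control(values, groups, cultures, control_group="control")
    ko_mean = float(summary.loc[summary["group"] == "KO", "mean"].iloc[0])
    report = stats_mod.run_comparison(
        {g: table.loc[table["group"] == g, "normalized"].to_numpy() for g in ("control", "KO")}
    )

    rng = np.random.default_rng(seed + 1)
    rejections = 0
    for _ in range(n_null_reps):
        a = rng.normal(0.0, 1.0, n_per_group_null)
        b = rng.normal(0.0, 1.0, n_per_group_null)
        null_report = stats_mod.run_comparison({"a": a, "b": b})
        rejections += null_report.p_value < alpha
    return {
        "true_ratio": true_ratio,
        "recovered_ratio": ko_mean,
        "effect_p_value": float(report.p_value),
        "effect_test": report.test_name,
        "n_null_reps": n_null_reps,
        "type_i_error": rejections / n_null_reps,
    }
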