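#!/usr/bin/env python
"""Confocal synaptic-intensity quantification on a simulated knockout cohort.

Simulates 3 cultures x (control, KO) x 5 images of synaptic puncta with a
planted 0.65x KO protein level, then runs the measurement chain: 1.4-um
rolling-average background subtraction, puncta ROIs from the vesicle
marker, per-ROI protein means, and per-culture control normalization.
Output: results/confocal/measurements.csv
"""

from pathlib import Path

from azquant import confocal as conf
from azquant.synth import SceneSpec, simulate_confocal_cohort

OUT = Path("results/confocal")
SEED = 7


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    scene = SceneSpec(
        shape=(160, 160), pixel_size_nm=100.0, psf_sigma_nm=0.0,
        background_level=20.0, noise_model="poisson", seed=SEED,
    )
    records, truth = simulate_confocal_cohort(
        scene, {"control": 1.0, "KO": 0.65}, n_cultures=3, images_per_group=5,
        base_intensity=100.0, punctum_cv=0.1, seed=SEED,
    )
    values, groups, cultures = [], [], []
    for rec in records:
        img = rec["stack"]
        marker = conf.subtract_local_background(img.frame(0, 0), img.pixel_size_nm, diameter_um=1.4)
        protein = conf.subtract_local_background(img.frame(0, 1), img.pixel_size_nm, diameter_um=1.4)
        rois = conf.define_rois(marker, img.pixel_size_nm)
        _, image_mean = conf.measure_roi_means(protein, rois)
        values.append(image_mean)
        groups.append(rec["group"])
        cultures.append(rec["culture"])

    table, summary = conf.normalize_to_control(values, groups, cultures, control_group="control")
    table.to_csv(OUT / "measurements.csv", index=False)
    ko = summary.loc[summary.group == "KO"].iloc[0]
    print(f"Planted KO/control ratio: {truth.params['group_ratios']['KO']}")
    print(
        f"Recovered normalized KO mean = {ko['mean']:.3f} +/- {ko['sem']:.3f} "
        f"(n = {int(ko['n'])} images, 3 cultures)."
    )


if __name__ == "__main__":
    main()
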