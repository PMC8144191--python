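#!/usr/bin/env python
"""Simulate a condensate time-lapse: two droplets fuse, the product relaxes.

Writes the movie (TIFF), the analytic ground truth, and prints the planted
relaxation parameters.  Output: results/droplets/
"""

from pathlib import Path

from azquant.io import write_image_stack
from azquant.synth import DropletSpec, FusionEventSpec, SceneSpec, render_droplet_movie

OUT = Path("results/droplets")
SEED = 7


def simulate(seed: int = SEED):
    scene = SceneSpec(
        shape=(96, 96), pixel_size_nm=100.0, frame_interval_s=1.0,
        psf_sigma_nm=90.0, noise_model="poisson", background_level=5.0, seed=seed,
    )
    droplets = [
        DropletSpec(center_xy=(32.0, 48.0), radius_nm=700.0, intensity=120.0),
        DropletSpec(center_xy=(48.0, 48.0), radius_nm=700.0, intensity=120.0),
        DropletSpec(center_xy=(70.0, 24.0), radius_nm=800.0, intensity=120.0),
    ]
    events = [FusionEventSpec(parent_ids=(0, 1), fusion_frame=6, tau_s=7.41, ar_inf=1.0)]
    return render_droplet_movie(scene, droplets, events, n_frames=50)


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    stack, truth = simulate()
    write_image_stack(OUT / "droplets.tif", stack)
    truth.write(OUT)
    ev = truth.events[0]
    print(f"Simulated {stack.n_frames} frames at {stack.pixel_size_nm} nm/px, 1 Hz.")
    print(
        f"Planted fusion at frame {ev['frame']}: AR relaxes from {ev['ar_0']:.2f} "
        f"toward {ev['ar_inf']:.2f} with tau = {ev['tau_s']} s."
    )
    print(f"Wrote {OUT/'droplets.tif'} and ground truth tables.")


if __name__ == "__main__":
    main()
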