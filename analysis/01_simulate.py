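#!/usr/bin/env python
"""Generate the demo inputs: a planted-triplet scene, blink trains rendered
to a small raw sCMOS stack, and a bead calibration field.

Writes under results/demo/: scene.csv (+ scene.json), stack.tif, camera.h5,
beads_src.csv, beads_ref.csv.
"""

from pathlib import Path

import numpy as np

from tricolo.io import write_camera, write_frames, write_localization_table, write_scene
from tricolo.pipeline import default_true_map
from tricolo.simulate import (CameraModel, GroundTruthScene, render_frames,
                              simulate_bead_field, simulate_blinking,
                              simulate_triplet_scene)

OUT = Path("results/demo")
OUT.mkdir(parents=True, exist_ok=True)
SEED = 2026

# --- ground-truth scene: 6x6 µm nucleus ROI with planted MCM-EdU-G4 triplets
scene = GroundTruthScene(roi_size_um=6.0, triplet_density_per_um2=5.0,
                         r1_nm=100.0, r2_nm=150.0, dtheta_rad=np.pi / 3,
                         background_per_um2=(10.0, 10.0, 10.0),
                         jitter_sd_nm=5.0, seed=SEED)
table = simulate_triplet_scene(scene)
write_scene(table, scene.to_dict(), OUT / "scene.csv")
n_trip = int((table.triplet_id >= 0).sum() // 3)
print(f"scene: {len(table)} points, {n_trip} planted triplets "
      f"-> {OUT/'scene.csv'}")

# --- a short raw stack of channel-1 emitters for the localization demo
cam = CameraModel.uniform((56, 56), pixel_size_nm=110.0, offset=100.0,
                          gain=2.0, readnoise_var=4.0, n_frames=50)
ch1 = table[(table.channel == 1) & table.in_roi].head(40)
trains = simulate_blinking(ch1, n_frames=cam.n_frames, mean_on_frames=3.0,
                           photons_per_frame=1000.0, seed=SEED + 1)
frames = render_frames(trains, cam, psf_sigma_nm=143.0,
                       background_photons=5.0, seed=SEED + 2)
write_frames(frames, OUT / "stack.tif")
write_camera(cam, OUT / "camera.h5")
print(f"stack: {cam.n_frames} frames of {len(trains)} blinking emitters "
      f"-> {OUT/'stack.tif'}")

# --- bead field under the channel-2 chromatic map
true_map = default_true_map(2, 6000.0)
src, ref = simulate_bead_field(80, true_map, field_size_nm=6000.0,
                               loc_noise_sd_nm=2.0, seed=SEED + 3)
for tab, name in ((src, "beads_src"), (ref, "beads_ref")):
    tab = tab.assign(frame=0, channel=1, photons=5000.0, background=1.0,
                     crlb_x_nm=2.0, crlb_y_nm=2.0, n_merged=1)
    write_localization_table(tab, OUT / f"{name}.csv")
print(f"beads: 80 pairs under a quadratic chromatic warp -> {OUT}/beads_*.csv")
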