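# vialtrack

Automated locomotion measurement for fruit flies climbing in vertical vials.
A fixed camera views up to four backlit 75 × 13 mm tubes (640 × 480 px,
30 frames/s, 10 s recordings); `vialtrack` detects the flies as dark blobs,
links them into trajectories, and reduces each vial recording to a panel of
kinetic descriptors normalized by the number of flies present:

- mean / maximum velocity (mm/s)
- total walking duration (s, per fly) and total walking distance (mm)
- percent of time in motion (speed strictly above the 2.5 mm/s cutoff)
- mean trajectory length per fly and per episode (mm), trajectory counts

Walking episodes ("trajectories") are maximal runs of frames at or above
2 mm/s — slower movement is not counted as progressive locomotion. Cohort
statistics (Kaplan–Meier lifetime curves, pairwise log-rank tests, one-way
ANOVA with Fisher's LSD) complete the screening workflow.

A built-in synthetic arena generates ground-truth trajectories from a
two-state pause/walk model (with a post-startle upward drift) and renders
them to frames, so the whole detection → tracking → descriptor stack is
testable without recorded video.

## Command line

```sh
# synthesize a recording (frames + ground-truth CSV)
vialtrack simulate --config sim.yaml --out run/ --seed 1

# full pipeline on synthetic or recorded frames
vialtrack run --simulate --seed 1 --out run/
vialtrack run --frames run/frames --out analysis/

# individual stages
vialtrack detect  --frames run/frames --n-vials 4 --out detections.csv
vialtrack track   --detections detections.csv --fps 30 --out tracks.csv
vialtrack analyze --tracks tracks.csv --counts counts.csv --out kinetics.csv

# cohort statistics and figures
vialtrack survival --in lifespans.csv --pairs "ctrl:treated"
vialtrack compare  --kinetics kinetics.csv --descriptor mean_velocity_mm_s --by group
vialtrack report   --kinetics kinetics.csv --survival lifespans.csv --out figs/
```

Configuration is YAML/JSON with strict validation; every threshold
(`walk_threshold_mm_s`, `motion_cutoff_mm_s`, detection contrast/area,
tracking gate and gap limits) has a documented default and can be
overridden. `vialtrack run` writes a `manifest.json` recording the config
digest, seed, and all outputs.

## Formats

- frame sequences: zero-padded PNG directories with a `sequence.json`
  sidecar (fps, dimensions, vial layout); AVI/MP4 read if a codec plugin
  is available
- tracks: CSV `vial_id,fly_id,frame,t_s,x_mm,y_mm,interpolated`
- detections: CSV `frame,vial_id,cx_mm,cy_mm,area_px,peak_contrast`
- kinetics: one CSV row per vial with descriptor columns named as above
- lifespans: CSV `group,lifespan_days,event` (`died` / `censored`)

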