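# Small self-contained demonstration run: simulate the default
# influx-clearance phantom on a 16^3 grid and push it through the
# solver and regional metrics. Finishes in well under a minute on one CPU.
seed: 7
output_dir: glymflux_demo_out
simulate:
  shape: [16, 16, 16]
  n_frames: 15
  frame_interval_min: 10.0
  first_frame_time_min: 30.0
  noise_sd: 0.0
uromt:
  sigma: 0.002
  beta: 10000.0
  n_substeps: 10
  max_iters: 25
metrics:
  flux_threshold: 0.001
  trajectory_smooth_window: 1
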