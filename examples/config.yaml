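# Desk-scale pipeline configuration.
# Every block overrides the defaults in alphamicro.pipeline.PipelineConfig;
# omitted keys keep their defaults.

seed: 1
outdir: runs/demo

well:
  width: 220.0          # µm
  height: 220.0
  voxel_size: [0.4, 0.4, 0.4]   # coarse grid for interactive runs;
                                # confocal is [0.101, 0.101, 0.159]

population:
  n_cells: 12
  parent_intensity: 4.0e-4      # Thomas-process parents per µm²
  mean_offspring: 10.0
  cluster_sigma: 14.0           # µm
  bias_bins_um: [0.0, 400.0, 40]
  unbiased_reference_cells: 400

pk:
  fit: true
  concentrations_nM: [0.25, 0.5, 1.0, 2.5, 5.0, 10.0, 20.0, 30.0]
  assay_durations_min: [5, 30, 60, 120, 240, 480, 1440]
  noise_cv: 0.05
  exposure_min: 1440.0
  labeling:
    specific_activity: 1.0e-4   # Pb-212 isotopes per antibody at t = 0
    irf: 0.55

transport:
  events_per_compartment: 2000
  cross_events: 4000
  frame_time_min: 120.0

microdose:
  folds: 20000
  bins: 250
  dt_min: 1.0

survival:
  sf_table: null                # CSV (condition_nM, sf); null -> synthesize
  true_z0: 30.1                 # Gy^-1, used only when synthesizing
  noise_cv: 0.02

rbe:
  alpha: 0.169                  # Gy^-1, external-beam LQ reference
  beta: 0.056                   # Gy^-2
  levels: [0.1, 0.37, 0.5]

geometric:
  enabled: true
  cell_diameter: 18.0           # µm
  nucleus_diameter: 10.0
  events_per_compartment: 2000
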