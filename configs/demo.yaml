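# Bundled demo run: multi-basin seascape, 31 coastal sites, salinity gradient.
# All values are the package defaults, spelled out for editing.
seed: 42
output_dir: runs/demo
grid:
  nx: 60
  ny: 40
  cell_size_km: 10.0
schedule:
  particles_per_cell: 20
  pld_days: 5.0
  dt_s: 3600.0
analysis:
  generations: 64
  symmetrization: mean
  theta_grid: [0.001, 0.002, 0.003]
  n_perm: 999
  mds_axes: 2
  flagged_region: SBO
  genic: none
demography:
  deme_size: 500
  migration_rate: 0.02
  n_loci: 1000
  n_generations: 140
  n_sample_per_site: 20
  missing_rate: 0.0
founder:
  enabled: true
  founder_size: 8
  interval: 4
  start_generation: 1
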