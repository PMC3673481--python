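# Full synthetic chain at desk scale: seapop all --config examples/config.yaml --seed 1 --out results/
seed: 1
stages: all
seascape: {nx: 60, ny: 40, span_days: 40.0}
sites: {n_sites: 15}
release:
  particles_per_cell: 100
  releases_per_year: 20
  n_years: 1
  duration_days: 21.0
  dt_hours: 2.0
  spring_window: [0.0, 18.0]
connectivity: {n_generations: 30, threshold: 1.0e-20, floor: 1.0e-60}
demography: {Ne: 200, n_neutral_loci: 59, n_generations: 400, sample_size: 47}
outliers: {n_sims: 20000}
assoc: {n_permutations: 999}
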