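# Packaged default configuration.
# Utility matrix, softmax temperature, and demographic rates are the
# calibrated defaults described in docs/methods.md; all are overridable.
landscape:
  n_rows: 40
  n_cols: 40
  pixel_size_m: 30.0
choice:
  temperature: 0.02
  deterministic: false
utility:
  grassland:
    birds: 0.931956
    carbon: 0.233134
    water_quality: 0.404895
    financial_profit: 0.93405
    biodiversity: 0.925844
  agriculture:
    birds: 0.05
    carbon: 0.2
    water_quality: 0.2
    financial_profit: 1.0
    biodiversity: 0.05
  forest:
    birds: 0.852241
    carbon: 0.229061
    water_quality: 0.376771
    financial_profit: 0.96189
    biodiversity: 0.903928
demography:
  nest_density_per_grass_pixel: 0.30
  nest_survival_base: 0.187832
  edge_penalty: 0.340352
  fledglings_per_successful_nest: 2.0
  occupancy_by_cover:
    grassland: 1.0
    agriculture: 0.8
    forest: 0.9
  stopover_survival_by_cover:
    grassland: 0.999555
    agriculture: 0.986178
    forest: 0.989822
  winter_survival_by_cover:
    grassland: 0.964549
    agriculture: 0.929288
    forest: 0.940041
  k_breeding_per_grass_pixel: 1.0
  k_stopover_per_grass_pixel: 3.0
  k_winter_per_grass_pixel: 2.0
  matrix_survival_floor: 0.10
simulation:
  n0: 100.0
  horizon: 30
  replicates: 100
  stochastic: false
response_curve:
  agriculture_share: 0.5
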