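# Experiment configuration. Omitted factors keep their full default level
# lists; omitted parameters keep package defaults.
factors:
  rcp: [RCP2.6, RCP4.5, RCP8.5]
  disturbance_response: [constant, linear, exponential]
  forest_age: [mature, young]
  forest_type: [BD, NE]
  harvest_intensity: [0.0, 0.5, 1.0, 1.5]
  salvage: [yes, no]
  material_usage: [1.0, 1.5]
  cascade: [1.0, 1.5]
  decarb_2050: [0.25, 0.50, 0.75]

sites: [site0]
seed: 1
n_patches: 10          # 100 reproduces the reference setup but is slower
noise_sd: 0.25         # interannual temperature noise, degC
gamma_shape: 2.0       # product decay Gamma shape (all pools)
df_material: 1.5       # tC avoided per tC product
df_fuel: 0.67          # tC avoided per tC burned
horizons: [2050, 2100]

stand:
  npp_max: 0.714             # kgC/m2/yr potential woody gain
  carrying_capacity: 60.0    # kgC/m2
  background_mortality: 0.01
  harvest_fraction: 0.24
  harvest_interval_ne: 20
  harvest_interval_bd: 25
  disturbance_interval_ne: 300
  disturbance_interval_bd: 1000
  deadwood_k: 0.04
  humification: 0.3
  soil_k: 0.01
  q10: 2.0

harvest:
  stem_fraction: 0.65
  harvest_efficiency: 0.90
  salvage_efficiency: 0.75
  branch_fraction: 0.13
  branch_removed_burned: 0.40
  salvage_trees_left: 0.20
  firewood_age_threshold: 20
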