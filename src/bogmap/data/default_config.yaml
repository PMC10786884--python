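# Packaged default pipeline configuration (small, quick-running scene).
# Class order everywhere: cutaway, cutover, grassland, forestry,
# remnant_peatland, water, built_up.

width: 120
height: 120
proportions: [0.10, 0.11, 0.43, 0.21, 0.13, 0.01, 0.01]
patch_scale: 12
pixel_size_ha: 0.01

n_scenes: 8
cloud_fraction_range: [0.05, 0.30]
noise_sd: 0.01
max_cloud_fraction: 0.10

n_per_class: [6, 6, 10, 8, 6, 3, 3]
polygon_size: 3

n_trees: 20
variables_per_split: sqrt

total_n: 350
min_per_stratum: 20
label_error_rate: 0.0

# null -> packaged default emission-factor table
ef_table: null

seed_truth: 101
seed_scenes: 202
seed_polygons: 303
seed_model: 404
seed_validation: 505
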