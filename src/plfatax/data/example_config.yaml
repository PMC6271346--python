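# Example end-to-end pipeline configuration.
#
# Stages run in the fixed order shown; any suffix may be omitted.  With a
# `simulate` stage the pipeline is self-contained (synthetic seston,
# isolates and consumers generated from the packaged ratio matrix);
# otherwise provide `inputs:` paths to your own CSV tables.
seed: 1
stages: [simulate, build-matrix, unmix, markers, trophic, ordination]

simulate:
  preset: heterotroph_dominated   # or green_algae_dominated / cyanobacteria_mixed
  n_samples: 20
  cv: 0.10                        # multiplicative compositional noise
  n_per_taxon: 5                  # isolates per taxon
  retention:                      # consumer selective retention factors
    "20:5ω3": 3.0
    "22:6ω3": 3.0

build-matrix:
  min_mean_pct: 1.0               # drop FAs under 1% mean weight in every taxon
  drop_single_species: true

unmix:
  protocol: plain                 # plain | latasa (successive runs) | wright (randomized starts)
  bound_factor: 1.5               # ±50% ratio adjustment bound
  # membership:                   # optional per-location taxon subsets
  #   pondA: [Proteobacteria, "Green algae", Diatoms]

markers:
  relative: true                  # fractions of marker FA (false: of total FA)
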