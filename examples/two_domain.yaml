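# Synthetic end-to-end demo: a two-domain elastic network with a known
# community structure, a planted-metastable Markov chain for the MSM
# stage, and apo/holo energy tables with ten 10-sigma outlier pairs.
output_dir: results/two_domain_demo
seed: 17
synthetic:
  kind: two_domain
  n_frames: 20000
markov:
  n_steps: 100000
  lag: 1
  macrostates: 3
coupling:
  synthetic:
    n_pairs: 200
    planted_outliers:
      - [0, 10.0]
      - [1, 10.0]
      - [2, 10.0]
      - [3, 10.0]
      - [4, 10.0]
      - [5, 10.0]
      - [6, 10.0]
      - [7, 10.0]
      - [8, 10.0]
      - [9, 10.0]
contact_cutoff: 4.5
contact_occupancy: 0.75
mask_threshold: 0.3
min_community_size: 3
coupling_threshold: 0.25
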