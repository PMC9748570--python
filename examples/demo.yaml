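# Demo run: synthetic 60-participant cohort, NS weighting, simulated score
# grid with one planted effect mirroring a realistic negative association
# between genome-wide risk and visual-subnetwork strength.
output_dir: demo_out
cohort:
  n_participants: 60
weightings: [NS]
threshold: 5
score_source: simulated
n_perm: 500
minp: flagged
hub_sample: 20
seed: 42
planted_effects:
  - target_phenotype: visual_mean_strength
    effect_r: -0.5
    score: genome_wide
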