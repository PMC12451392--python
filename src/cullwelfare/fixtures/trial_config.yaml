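# Trial-like synthetic dataset: 390 animals over 17 sorties, arm sizes 94-100,
# all animals killed.  Arm sizes are fixed so the margins match the study
# design; everything else is drawn from the generator's distributions.
seed: 20230220
n_sorties: 17
n_per_arm:
  RIFLE_308: 100
  BUCK_00: 97
  BUCK_1: 99
  BUCK_4: 94
ct_mu_log: 4.0943445622221005
ct_sigma_log: 0.8
p_instant_per_ammo:
  RIFLE_308: 0.07
  BUCK_00: 0.03
  BUCK_1: 0.05
  BUCK_4: 0.05
censor_prob: 0.23
shots_mean: 2.6
pellet_hit_prob: 0.22
zone_weights:
  HEAD: 0.05
  NECK: 0.10
  THORAX: 0.60
  ABDOMEN: 0.15
  LIMBS: 0.10
postmortem_fraction: 0.20
ex_situ_fraction: 0.78
group_mean_size: 3.33
sex_age_probs:
  ADULT_M: 0.68
  ADULT_F: 0.20
  YEARLING: 0.07
  FAWN: 0.05
zone_scatter_per_ammo:
  RIFLE_308: 0.0
  BUCK_00: 0.15
  BUCK_1: 0.30
  BUCK_4: 0.50
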