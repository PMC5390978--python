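# Simulate a six-release MRR experiment on the 200-trap grid and run the
# full analysis. The kernel parameters are the fitted study population.
mode: simulate
seed: 7
stages: [stats, glm, diffusion, kernel, directionality]
jackknife: false
n_boot: 1000
sim:
  seed: 7
  n_releases: 6
  n_flyers_per_release: 20000
  design_id: D200
  capture_radius: 3.0
  sex_ratio_male: 0.5
  kernel: {B1: 21.6, B2: 1022.0, pi_LD: 0.80}
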