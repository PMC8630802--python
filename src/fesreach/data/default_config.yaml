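arm:
  L1: 0.32922
  L2: 0.35400000000000004
  m1: 2.24
  m2: 1.7599999999999998
  I1: 0.07132126090615146
  I2: 0.15084475395264002
  c1: 0.14353992000000002
  c2: 0.24142800000000003
  force_scale: 1.0
  dt: 0.02
  damping: 0.1
  substeps: 1
  joint_limits_deg:
  - - -10.0
    - 170.0
  - - 0.0
    - 160.0
muscles:
- name: anterior_deltoid
  Fmax: 800.0
  l_opt: 0.1
  r_shoulder: 0.04
  r_elbow: 0.0
  l_ref: 0.13839724354387525
  tau_act: 0.015
  tau_deact: 0.05
  v_max: 10.0
- name: posterior_deltoid
  Fmax: 800.0
  l_opt: 0.1
  r_shoulder: -0.04
  r_elbow: 0.0
  l_ref: 0.06160275645612476
  tau_act: 0.015
  tau_deact: 0.05
  v_max: 10.0
- name: brachialis
  Fmax: 1000.0
  l_opt: 0.1
  r_shoulder: 0.0
  r_elbow: 0.03
  l_ref: 0.12879793265790646
  tau_act: 0.015
  tau_deact: 0.05
  v_max: 10.0
- name: triceps_short
  Fmax: 1000.0
  l_opt: 0.1
  r_shoulder: 0.0
  r_elbow: -0.03
  l_ref: 0.07120206734209357
  tau_act: 0.015
  tau_deact: 0.05
  v_max: 10.0
- name: biceps
  Fmax: 700.0
  l_opt: 0.1
  r_shoulder: 0.025
  r_elbow: 0.035
  l_ref: 0.15759586531581288
  tau_act: 0.015
  tau_deact: 0.05
  v_max: 10.0
- name: triceps_long
  Fmax: 700.0
  l_opt: 0.1
  r_shoulder: -0.025
  r_elbow: -0.035
  l_ref: 0.04240413468418712
  tau_act: 0.015
  tau_deact: 0.05
  v_max: 10.0
task:
  timeout_steps: 50
  dwell_steps: 5
  radius: 0.075
  step_penalty: -0.1
  target_reward: 1.0
  activation_penalty_coef: 0.245
  in_target_reward_mode: per_step
  spawn_box_deg:
  - - 20.0
    - 90.0
  - - 20.0
    - 90.0
agent:
  algorithm: TD3
  use_her: true
  hidden_layers: 2
  units_per_layer: 64
  exploration_eps: 0.3
  her_k: 4
  her_strategy: future
  gamma: 0.98
  tau: 0.005
  actor_lr: 0.001
  critic_lr: 0.001
  batch_size: 256
  buffer_capacity: 1000000
  policy_delay: 2
  target_noise: 0.2
  noise_clip: 0.5
  seed: 0
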