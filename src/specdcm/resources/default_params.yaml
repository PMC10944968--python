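background_drive:
- 0.05
- 0.05
- 0.05
- 0.05
capacitance:
- 0.01
- 0.01
- 0.005
- 0.01
g_leak:
- 1.0
- 1.0
- 1.0
- 1.0
innovations_amp: 1.0
innovations_exponent: 1.0
innovations_f_clamp: 1.0
innovations_floor: 0.25
kappa_exc:
- 250.0
- 250.0
- 250.0
- 250.0
kappa_inh:
- 62.5
- 62.5
- 62.5
- 62.5
lateral_mix: 0.5
obs_gain: 1.0
obs_noise_psd: 0.0001
sigmoid_slope: 6.0
sigmoid_threshold: -54.0
v_exc: 60.0
v_inh: -90.0
v_leak: -70.0
w_dp_sp: 0.5
w_feedback: 0.08
w_feedforward: 0.1
w_from_ii:
- 1.0
- 1.0
- 0.0
- 1.0
w_ii_exc:
- 0.4
- 0.4
- 0.2
w_lateral: 0.08
w_self_inh:
- 0.2
- 0.2
- 0.4
- 0.2
w_sp_ss: 0.6
w_ss_sp: 0.4
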