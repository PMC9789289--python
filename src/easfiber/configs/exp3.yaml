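# Experiment 3: combined electric-acoustic stimulation
experiment_id: 3
n_lsr: 30
n_msr: 30
n_hsr: 90
seed: 0
dt: 1.0e-6
burn_in: 20.0e-3
hearing_loss: 26.0
pulse_rate: 250.0
train_phase_width: 40.0e-6
as_durations: [0.1, 0.2, 0.3]
as_level_range: [70.0, 100.0]
as_level_step: 5.0
as_rate_criterion: 2.5
n_es_levels: 4
n_reps_exp3: 2
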