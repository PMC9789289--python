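# Experiment 2: 250 pps biphasic trains, electric-only, three variants
experiment_id: 2
n_lsr: 30
n_msr: 30
n_hsr: 90
seed: 0
dt: 1.0e-6
burn_in: 20.0e-3
hearing_loss: 26.0
pulse_rate: 250.0
train_phase_width: 40.0e-6
train_duration: 0.3
n_train_presentations: 20
variants: [es-alone, uncoupled, coupled]
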