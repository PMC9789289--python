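# Experiment 1: monophasic single pulses, ES-alone population
experiment_id: 1
n_lsr: 30
n_msr: 30
n_hsr: 90
seed: 0
dt: 1.0e-6
burn_in: 20.0e-3
n_trials_fe: 100
phase_widths: [26.0e-6, 39.0e-6]
polarities: [cathodic, anodic]
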