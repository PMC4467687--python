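c_values:
- 0.6
- 0.75
- 0.9
cap_ps: 100000.0
delta: 50.0
hellinger_n: 10000
k_values:
- 0.5
- 0.8
- 0.9
- 0.95
- 0.99
- 1.01
- 1.05
- 1.1
- 1.2
- 2.0
m: 200
n_photons: 50
n_reps: 1000
seed: 0
tau1: 1500.0
tau1_known: true
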