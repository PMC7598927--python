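# Wildtype base, unlimited-repair-capacity regime (R = inf).
# Non-dimensional base values are repository calibration (see docs/methods.md).
g: 2.0
k1: 0.4
k2: 0.092
Q: 0.5
R: inf
re: 0.2957
s: 0.64
P_div: 0.5
D_death: 1.0
D_health: 0.5
sigma: 0.005
n_founders: 5
max_generation: 2
max_divisions: 1000
max_lifetime: 10000.0
seed: 1
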