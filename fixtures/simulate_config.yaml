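# SimulationConfig overrides for `anc-delivery simulate`.
# Omitted fields keep the package defaults (see docs/methods.md).
n: 5000
rho: -0.4
delta: 1.0
gamma_iv: 1.0
first_trimester_rate: 0.40
seed: 12345
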