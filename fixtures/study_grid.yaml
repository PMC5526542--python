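# StudyGrid for `anc-delivery study`: small demonstration grid.
rhos: [-0.4, 0.0, 0.4]
gamma_ivs: [1.0]
ns: [2000]
replicates: 25
seed: 12345
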