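# Default synthetic study design: 3 groups x 10 animals x 14 regions.
# Any SyntheticConfig field may be set here; unset fields keep their
# documented defaults (see docs/methods.md).
n_animals: 10
nuclei_range: [300, 800]
rho_within: 0.5
rho_between: 0.1
sigma: 0.5
delta_double: 0.01
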