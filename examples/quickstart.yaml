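# Minimal run: one O2 challenge and the combined challenge, tabular only.
protocols: [O2_7to2, combined]
n_capillaries: 100
noise_sd:
  velocity: 20.0
  lineal_density: 5.0
  so2: 2.0
amplitude_sd:
  velocity: 30.0
seed: 1
outdir: out
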