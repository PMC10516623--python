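# Ligand-free pre-folded demo: 60-s movies at the default operating point.
scenario:
  mode: prefolded
  duration: 60.0
scheme:
  archetype_weights: [0.29, 0.16, 0.55]
n: 200
seed: 4
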