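# Van der Waals radii (Å) used for the solvent-excluded-surface grid.
# Elements not listed fall back to `default`.
radii:
  C: 1.70
  N: 1.55
  O: 1.52
  S: 1.80
  P: 1.80
default: 1.70
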