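# Anthropometric segment parameter tables.
# Per segment: mass fraction of whole-body mass (one leg), centre-of-mass
# position as a fraction of segment length from the proximal end, and
# radius of gyration about the CoM as a fraction of segment length.
# "winter" is the standard cadaver-based table used in link-segment
# biomechanics (foot/shank/thigh rows).
winter:
  foot:  {mass_frac: 0.0145, com_frac: 0.50,  gyration_frac: 0.475}
  shank: {mass_frac: 0.0465, com_frac: 0.433, gyration_frac: 0.302}
  thigh: {mass_frac: 0.1000, com_frac: 0.433, gyration_frac: 0.323}
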