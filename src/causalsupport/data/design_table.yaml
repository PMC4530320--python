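# Packaged two-group, two-phase experimental design.
# Each entry is [n_effect, n_no_effect] for 20 presentations of that trial
# type in that phase; [0, 0] means the type did not occur in that phase.
# Trial types: CD = confounded compound, C = confounded target alone,
# IJ = interacting compound, I = interacting target alone, J = alternative
# alone, NM = no medicine (background only).
groups:
  C_strong_I_weak:
    phase1:
      CD: [16, 4]
      C: [0, 0]
      IJ: [8, 12]
      I: [0, 0]
      J: [0, 20]
      NM: [0, 20]
    phase2:
      CD: [16, 4]
      C: [16, 4]
      IJ: [8, 12]
      I: [0, 20]
      J: [0, 20]
      NM: [0, 20]
  C_weak_I_strong:
    phase1:
      CD: [16, 4]
      C: [0, 0]
      IJ: [16, 4]
      I: [0, 0]
      J: [8, 12]
      NM: [0, 20]
    phase2:
      CD: [16, 4]
      C: [0, 20]
      IJ: [16, 4]
      I: [16, 4]
      J: [8, 12]
      NM: [0, 20]
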