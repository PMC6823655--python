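# Default rule parameters for the nine-domain complexity scorer.
# Code-list keys may be inline lists of codes or paths (relative to this
# file) to one-code-per-line text files; when omitted the placeholder
# lists shipped with the package are used.
encounter_collapse_days: 7
nsba_threshold: 10
bp_systolic_threshold: 140.0
bp_diastolic_threshold: 90.0
bp_increment: 0.5
bmi_cutoffs:
  - [25.0, 0.25]
  - [30.0, 0.5]
  - [35.0, 0.75]
dx_elevation_threshold: 5
dx_elevation_increment: 1.0
phq9_threshold: 9
hcs_bins: [0.0, 15.0, 25.0, 50.0]
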