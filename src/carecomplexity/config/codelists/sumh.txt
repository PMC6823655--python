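# Placeholder substance-use / mental-health (SU/MH) code list.
# ICD-10 chapter-level examples; deployments substitute their own list.
F10
F11
F12
F19
F20
F25
F29
F31
F32
F33
F41
F43
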