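# Placeholder chronic neurodegenerative disorder code list.
G20
G30
G35
G10
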