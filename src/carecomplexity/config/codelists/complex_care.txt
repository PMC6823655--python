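# Placeholder complex-care eligibility code list (the operational list is
# maintained by the provincial General Practice Services Committee and is
# not redistributed here). One code per line.
E10
E11
I50
J44
N18
C34
B20
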