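compound,ug_per_cigarette
Acetaldehyde,2000
"1,3-butadiene/1-Butyne",130
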