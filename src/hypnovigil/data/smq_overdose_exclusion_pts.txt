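# Overdose-type PTs used by step 2 of the modified-SMQ selection: a case whose
# only SMQ hits are in this set, co-reported with a suicidal-behavior PT, is excluded.
Accidental overdose
Intentional overdose
Overdose
Prescribed overdose
Toxicity to various agents
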