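# Suicidal-behavior PTs for step 2 of the modified-SMQ selection. These are not
# members of the abuse SMQ; they are matched against all reactions of a case.
Completed suicide
Suicidal behavior
Suicide attempt
Suicide threat
Suspected suicide
Suspected suicide attempt
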