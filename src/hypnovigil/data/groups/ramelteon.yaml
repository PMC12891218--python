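# Ramelteon — unscheduled melatonin MT1/MT2 receptor agonist approved for insomnia.
ingredients:
  - ramelteon
synonyms:
  Rozerem: ramelteon
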