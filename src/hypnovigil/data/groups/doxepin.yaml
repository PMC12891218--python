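# Low-dose doxepin — unscheduled, FDA-approved for sleep-maintenance insomnia.
ingredients:
  - doxepin
synonyms:
  Silenor: doxepin
  Sinequan: doxepin
  Doxepin hydrochloride: doxepin
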