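# Benzodiazepines FDA-approved for insomnia (DEA Schedule IV).
ingredients:
  - estazolam
  - flurazepam
  - quazepam
  - temazepam
  - triazolam
synonyms:
  Prosom: estazolam
  Dalmane: flurazepam
  Flurazepam hydrochloride: flurazepam
  Doral: quazepam
  Restoril: temazepam
  Halcion: triazolam
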