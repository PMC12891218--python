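# Non-benzodiazepine GABA-A hypnotics ("Z-drugs", DEA Schedule IV).
ingredients:
  - zolpidem
  - zaleplon
  - eszopiclone
synonyms:
  Ambien: zolpidem
  Ambien CR: zolpidem
  Edluar: zolpidem
  Intermezzo: zolpidem
  Zolpimist: zolpidem
  Zolpidem tartrate: zolpidem
  Sonata: zaleplon
  Lunesta: eszopiclone
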