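# Benzodiazepines approved for any indication. Superset of the five agents
# approved for insomnia plus the common US benzodiazepines that are prescribed
# off-label as hypnotics; fully overridable via a user config.
ingredients:
  - estazolam
  - flurazepam
  - quazepam
  - temazepam
  - triazolam
  - alprazolam
  - lorazepam
  - clonazepam
  - diazepam
  - chlordiazepoxide
  - clorazepate
  - oxazepam
  - midazolam
  - clobazam
  - remimazolam
synonyms:
  Prosom: estazolam
  Dalmane: flurazepam
  Flurazepam hydrochloride: flurazepam
  Doral: quazepam
  Restoril: temazepam
  Halcion: triazolam
  Xanax: alprazolam
  Ativan: lorazepam
  Klonopin: clonazepam
  Valium: diazepam
  Librium: chlordiazepoxide
  Tranxene: clorazepate
  Serax: oxazepam
  Versed: midazolam
  Onfi: clobazam
  Sympazan: clobazam
  Byfavo: remimazolam
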