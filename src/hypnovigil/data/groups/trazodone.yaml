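# Trazodone — unscheduled antidepressant widely used off-label for insomnia;
# reference drug for the unscheduled comparisons.
ingredients:
  - trazodone
synonyms:
  Desyrel: trazodone
  Oleptro: trazodone
  Trazodone hydrochloride: trazodone
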