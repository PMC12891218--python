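# Dual orexin receptor antagonists approved for insomnia (DEA Schedule IV).
ingredients:
  - suvorexant
  - lemborexant
  - daridorexant
synonyms:
  Belsomra: suvorexant
  Dayvigo: lemborexant
  Quviviq: daridorexant
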