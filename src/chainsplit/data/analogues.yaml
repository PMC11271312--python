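# Bundled insulin analogue series: human insulin, the single substitutions,
# their combinations, acylated variants and icodec itself.
human_insulin: {}

A14E:
  substitutions: [A14E]

B16H:
  substitutions: [B16H]

B25H:
  substitutions: [B25H]

A14E_B25H:
  substitutions: [A14E, B25H]

A14E_B16H_B25H:
  substitutions: [A14E, B16H, B25H]

A14E_B25H_C18diacid:
  substitutions: [A14E, B25H]
  truncations: [desB30]
  modifications:
    - {block: C18diacid-gGlu-2xOEG, site: B29-NepsLys}

A14E_B25H_C20diacid:
  substitutions: [A14E, B25H]
  truncations: [desB30]
  modifications:
    - {block: C20diacid-gGlu-2xOEG, site: B29-NepsLys}

icodec:
  substitutions: [A14E, B16H, B25H]
  truncations: [desB30]
  modifications:
    - {block: C20diacid-gGlu-2xOEG, site: B29-NepsLys}
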