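# The seven major dementia types used by the disease-of-focus filter.
# Variants are the simplified names the filter matches (prefix mode), e.g.
# "Alzheimer's Disease" is represented by the stem "alzheimer".
category: dementia
entries:
  "Alzheimer's Disease":
    - alzheimer
  "Parkinson's Disease":
    - parkinson
  "Huntington's Disease":
    - huntington
  "Frontotemporal Dementia":
    - frontotemporal dementia
  "Lewy Body Dementia":
    - lewy body
  "Vascular Dementia":
    - vascular dementia
  "Mixed Dementia":
    - mixed dementia
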