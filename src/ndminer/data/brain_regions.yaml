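# Thirteen brain regions commonly studied in neurodegenerative disease.
category: brain_region
entries:
  "Amygdala":
    - amygdala
  "Basal ganglia":
    - basal ganglia
  "Brain stem":
    - brain stem
    - brainstem
  "Cerebellum":
    - cerebellum
  "Cingulate gyrus":
    - cingulate gyrus
  "Corpus callosum":
    - corpus callosum
  "Hippocampus":
    - hippocampus
  "Hypothalamus":
    - hypothalamus
  "Neocortex":
    - neocortex
  "Pituitary gland":
    - pituitary gland
  "Prefrontal cortex":
    - prefrontal cortex
  "Spinal cord":
    - spinal cord
  "Thalamus":
    - thalamus
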