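# Synthetic stand-in for the expert-curated list of 32 representative
# Alzheimer's-research keywords.  The published supplementary list is not
# redistributable here; this snapshot keeps the attested entries (tau
# deposition, innate immune response, mitochondria, lipid metabolism,
# oxidative stress, blood-brain barrier) and fills the remainder with
# representative process/pathology terms from the AD literature.  The code
# treats the list purely as configuration.
category: keyword
entries:
  "tau deposition":
    - tau deposition
  "innate immune response":
    - innate immune response
  "mitochondria":
    - mitochondria
    - mitochondrial
  "lipid metabolism":
    - lipid metabolism
  "oxidative stress":
    - oxidative stress
  "blood-brain barrier":
    - blood brain barrier
  "amyloid beta":
    - amyloid beta
  "neuroinflammation":
    - neuroinflammation
  "synaptic plasticity":
    - synaptic plasticity
  "microglia":
    - microglia
  "astrocyte":
    - astrocyte
    - astrocytes
  "neurofibrillary tangles":
    - neurofibrillary tangles
  "tau phosphorylation":
    - tau phosphorylation
  "apoptosis":
    - apoptosis
  "autophagy":
    - autophagy
  "cholinergic signaling":
    - cholinergic signaling
  "insulin resistance":
    - insulin resistance
  "cerebral amyloid angiopathy":
    - cerebral amyloid angiopathy
  "cognitive decline":
    - cognitive decline
  "memory impairment":
    - memory impairment
  "neurodegeneration":
    - neurodegeneration
  "endosomal trafficking":
    - endosomal trafficking
  "cholesterol metabolism":
    - cholesterol metabolism
  "gut microbiome":
    - gut microbiome
  "epigenetic regulation":
    - epigenetic regulation
  "proteostasis":
    - proteostasis
  "calcium homeostasis":
    - calcium homeostasis
  "axonal transport":
    - axonal transport
  "myelination":
    - myelination
  "adult neurogenesis":
    - adult neurogenesis
  "complement activation":
    - complement activation
  "vascular dysfunction":
    - vascular dysfunction
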