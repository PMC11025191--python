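# Synthetic snapshot of Alzheimer's-disease mouse-model strain names in the
# style of the MODEL-AD strain table (eleven strains).  Strain names serve as
# the primary identifiers matched in titles and abstracts; the live strain
# table is not redistributable, so this list mixes widely used community
# strain names with MODEL-AD-style knock-in designations.
category: mouse_model
entries:
  "5xFAD":
    - 5xfad
  "3xTg-AD":
    - 3xtg ad
  "APP/PS1":
    - app ps1
  "Trem2-R47H":
    - trem2 r47h
  "APOE4-KI":
    - apoe4 ki
  "hAbeta-KI":
    - habeta ki
  "hTau":
    - htau
  "LOAD1":
    - load1
  "LOAD2":
    - load2
  "Abca7-A1527G":
    - abca7 a1527g
  "Plcg2-M28L":
    - plcg2 m28l
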