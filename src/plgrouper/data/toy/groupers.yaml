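# Toy grouper definitions over the bundled toy ontology.
# Names and ranks follow the 21-grouper presentation order; only the systems
# represented in the toy hierarchy carry roots here. The real clinical build
# (~1211 concepts) is proprietary and is not reproduced.
groupers:
  - name: Oncology
    rank: 2
    include_roots: [363346000]   # malignant neoplastic disease
    exclude_roots: [372130007]   # malignant neoplasm of skin -> Dermatology
  - name: Cardiovascular and Peripheral Vascular
    rank: 3
    include_roots: [49601007]
  - name: Respiratory and Allergy
    rank: 4
    include_roots: [50043002]
  - name: Infectious Disease, Immune, or Lymphatic
    rank: 8
    include_roots: [40733004]
  - name: Dermatology
    rank: 15
    include_roots: [95320005]
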