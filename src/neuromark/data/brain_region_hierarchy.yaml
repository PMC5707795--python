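# Default anatomical hierarchy of brain regions used to group purified-cell
# samples.  Samples annotated at a node participate in marker selection for
# that node and all of its ancestors; glial cross-region inclusion is
# expressed through per-sample override_regions, not here.
name: whole brain
children:
  - name: cerebrum
    children:
      - name: cortex
      - name: hippocampus
      - name: amygdala
      - name: basal forebrain
      - name: striatum
  - name: thalamus
  - name: brainstem
    children:
      - name: midbrain
      - name: locus coeruleus
  - name: cerebellum
  - name: spinal cord
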