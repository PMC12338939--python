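# Default descriptor vocabulary, version 1.
# Each field is a closed option set; the synthesizer never emits a
# descriptor outside these lists.
skin_structure:
  - smooth
  - scaly
  - ulcerated
  - raised
  - flat
image_color:
  - light brown
  - dark brown
  - black
  - pink
  - red
  - blue-gray
dermoscopic_structures:
  - pigment network
  - globules
  - streaks
  - dots
  - structureless areas
  - arborizing vessels
symmetry:
  - symmetric
  - asymmetric
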