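# Expert-defined sub-period intervals (percent of word duration) over which
# each kinematic measurement characterises a word for the jaw-range and
# jaw-control criteria.  Papa carries two open-close gestures and therefore
# two intervals per criterion.
Ba:
  jaw_range: [[20, 60]]
  jaw_control: [[10, 40]]
Eye:
  jaw_range: [[20, 60]]
  jaw_control: [[10, 40]]
Map:
  jaw_range: [[10, 50]]
  jaw_control: [[5, 70]]
Um:
  jaw_range: [[0, 70]]
  jaw_control: [[0, 70]]
Ham:
  jaw_range: [[10, 60]]
  jaw_control: [[10, 60]]
Papa:
  jaw_range: [[10, 40], [45, 80]]
  jaw_control: [[10, 40], [45, 80]]
Bob:
  jaw_range: [[10, 50]]
  jaw_control: [[10, 50]]
Pam:
  jaw_range: [[10, 60]]
  jaw_control: [[10, 60]]
Pup:
  jaw_range: [[10, 50]]
  jaw_control: [[10, 50]]
Pie:
  jaw_range: [[15, 50]]
  jaw_control: [[15, 50]]
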