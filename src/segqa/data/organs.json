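{
  "head_and_neck": [
    "brain",
    "brainstem",
    "eye_globe_right",
    "eye_globe_left",
    "lens_right",
    "lens_left",
    "optic_nerve_right",
    "optic_nerve_left",
    "parotid_right",
    "parotid_left",
    "submandibular_right",
    "submandibular_left",
    "mandible"
  ],
  "chest": [
    "heart",
    "lung_right",
    "lung_left",
    "spinal_cord",
    "esophagus",
    "breast_right",
    "breast_left"
  ],
  "abdomen": [
    "liver",
    "spleen",
    "kidney_right",
    "kidney_left"
  ],
  "pelvis": [
    "prostate",
    "seminal_vesicle",
    "bladder",
    "rectum"
  ]
}
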