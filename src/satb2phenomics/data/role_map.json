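{
  "description": "Canonical 36-point facial landmark scheme: 8 midline points (forehead to chin) and 14 left/right pairs. Template coordinates are in a 200x200 reference frame with the facial midline at x=100; x grows rightward, y downward, origin top-left. 'left' means the smaller-x side of the image.",
  "reference_frame": [200, 200],
  "midline_x": 100.0,
  "midline": [0, 1, 2, 3, 4, 5, 6, 7],
  "pairs": [
    [8, 22], [9, 23], [10, 24], [11, 25], [12, 26], [13, 27], [14, 28],
    [15, 29], [16, 30], [17, 31], [18, 32], [19, 33], [20, 34], [21, 35]
  ],
  "names": [
    "forehead", "glabella", "nasion", "nose_tip", "philtrum",
    "upper_lip_center", "lower_lip_center", "chin",
    "brow_inner_L", "brow_mid_L", "brow_outer_L",
    "eye_inner_L", "eye_top_L", "eye_outer_L", "eye_bottom_L",
    "nasal_ala_L", "mouth_corner_L", "cupid_L",
    "cheekbone_L", "mid_cheek_L", "jaw_angle_L", "jaw_lower_L",
    "brow_inner_R", "brow_mid_R", "brow_outer_R",
    "eye_inner_R", "eye_top_R", "eye_outer_R", "eye_bottom_R",
    "nasal_ala_R", "mouth_corner_R", "cupid_R",
    "cheekbone_R", "mid_cheek_R", "jaw_angle_R", "jaw_lower_R"
  ],
  "template": [
    [100.0, 30.0], [100.0, 55.0], [100.0, 70.0], [100.0, 105.0],
    [100.0, 118.0], [100.0, 128.0], [100.0, 142.0], [100.0, 172.0],
    [82.0, 58.0], [70.0, 54.0], [58.0, 58.0],
    [85.0, 72.0], [75.0, 68.0], [65.0, 72.0], [75.0, 76.0],
    [86.0, 106.0], [76.0, 135.0], [90.0, 127.0],
    [55.0, 95.0], [60.0, 120.0], [68.0, 148.0], [82.0, 164.0],
    [118.0, 58.0], [130.0, 54.0], [142.0, 58.0],
    [115.0, 72.0], [125.0, 68.0], [135.0, 72.0], [125.0, 76.0],
    [114.0, 106.0], [124.0, 135.0], [110.0, 127.0],
    [145.0, 95.0], [140.0, 120.0], [132.0, 148.0], [118.0, 164.0]
  ]
}
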