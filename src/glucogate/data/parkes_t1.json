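{
  "name": "parkes-t1",
  "version": 1,
  "diabetes_type": 1,
  "units": "mg/dl",
  "domain": [0, 550],
  "source": "Parkes consensus error grid, type 1 diabetes; vertex coordinates as tabulated by Pfutzner et al., J Diabetes Sci Technol 7(5):1275-1281 (2013)",
  "zones": {
    "A": [
      [0, 0], [0, 50], [30, 50], [140, 170], [280, 380], [430, 550],
      [550, 550], [550, 450], [385, 300], [170, 145], [50, 30], [50, 0]
    ],
    "B_upper": [
      [0, 50], [0, 60], [30, 60], [50, 80], [70, 110], [260, 550],
      [430, 550], [280, 380], [140, 170], [30, 50]
    ],
    "B_lower": [
      [50, 0], [120, 0], [120, 30], [260, 130], [550, 250], [550, 450],
      [385, 300], [170, 145], [50, 30]
    ],
    "C_upper": [
      [0, 60], [0, 100], [25, 100], [50, 125], [80, 215], [125, 550],
      [260, 550], [70, 110], [50, 80], [30, 60]
    ],
    "C_lower": [
      [120, 0], [250, 0], [250, 40], [550, 150], [550, 250], [260, 130],
      [120, 30]
    ],
    "D_upper": [
      [0, 100], [0, 150], [35, 155], [50, 550], [125, 550], [80, 215],
      [50, 125], [25, 100]
    ],
    "D_lower": [
      [250, 0], [550, 0], [550, 150], [250, 40]
    ],
    "E_upper": [
      [0, 150], [0, 550], [50, 550], [35, 155]
    ]
  }
}
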