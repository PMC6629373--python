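{
  "alpha5": [
    "H5.01",
    "H5.02",
    "H5.03",
    "H5.04",
    "H5.05",
    "H5.06",
    "H5.07",
    "H5.08",
    "H5.09",
    "H5.10",
    "H5.11",
    "H5.12",
    "H5.13",
    "H5.14",
    "H5.15",
    "H5.16",
    "H5.17",
    "H5.18",
    "H5.19",
    "H5.20",
    "H5.21",
    "H5.22",
    "H5.23",
    "H5.24",
    "H5.25",
    "H5.26"
  ],
  "alpha5_frame": [
    "H5.11",
    "H5.12",
    "H5.13",
    "H5.14",
    "H5.15",
    "H5.16",
    "H5.17",
    "H5.18",
    "H5.19",
    "H5.20",
    "H5.21",
    "H5.22",
    "H5.23",
    "H5.24",
    "H5.25",
    "H5.26"
  ],
  "alpha5_hook": [
    "H5.22",
    "H5.23",
    "H5.24",
    "H5.25",
    "H5.26"
  ]
}
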