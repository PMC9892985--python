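{
  "schema_version": 1,
  "superfeatures": [
    "Dots",
    "Globules",
    "Lines",
    "Network structures",
    "Regression structures",
    "Shiny white structures",
    "Patterns",
    "Structureless areas",
    "Vessels"
  ],
  "mapping": {
    "Dots": ["Irregular dots", "Regular dots"],
    "Globules": [
      "Cobblestone pattern",
      "Irregular globules",
      "Regular globules",
      "Rim of brown globules"
    ],
    "Lines": ["Branched streaks", "Pseudopods", "Radial streaming", "Starburst"],
    "Network structures": [
      "Atypical pigment network",
      "Broadened pigment network",
      "Delicate pigment network",
      "Negative pigment network",
      "Typical pigment network"
    ],
    "Regression structures": ["Peppering / granularity", "Scarlike depigmentation"],
    "Shiny white structures": [],
    "Patterns": ["Angulated lines", "Polygons", "Zigzags"],
    "Structureless areas": [
      "Irregular blotches",
      "Regular blotches",
      "Blue-whitish veil",
      "Milky red areas",
      "Structureless brown areas / homogenous"
    ],
    "Vessels": [
      "Comma vessel",
      "Corkscrew vessel",
      "Dotted vessel",
      "Linear irregular vessel",
      "Polymorphous vessel",
      "Milky red globules"
    ]
  },
  "active": [
    "Dots",
    "Globules",
    "Lines",
    "Network structures",
    "Regression structures",
    "Vessels"
  ]
}
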