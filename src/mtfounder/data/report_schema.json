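{
 "type": "object",
 "required": ["provenance", "diversity", "haplogroup_composition",
              "founder_lineages", "founder_summary", "amova",
              "composition_chi2", "pathogenicity"],
 "properties": {
  "provenance": {
   "type": "object",
   "required": ["package_version", "seed", "inputs"],
   "properties": {
    "package_version": {"type": "string"},
    "seed": {"type": "number"},
    "inputs": {"type": "object"}
   }
  },
  "diversity": {"type": "object"},
  "haplogroup_composition": {"type": "object"},
  "founder_lineages": {
   "type": "array",
   "items": {
    "type": "object",
    "required": ["label", "haplogroup", "signature", "carrier_count",
                 "relative_frequency", "exclusivity", "ancestry_class"],
    "properties": {
     "label": {"type": "string"},
     "haplogroup": {"type": "string"},
     "signature": {"type": "string"},
     "carrier_count": {"type": "number"},
     "relative_frequency": {"type": "number"},
     "exclusivity": {"type": "string"},
     "ancestry_class": {"type": "string"}
    }
   }
  },
  "founder_summary": {"type": "object"},
  "amova": {"type": "object"},
  "composition_chi2": {"type": ["object", "null"]},
  "pathogenicity": {"type": ["array", "null"]}
 }
}
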