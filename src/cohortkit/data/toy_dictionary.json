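{
  "version": "toy-0.1",
  "properties": [
    {
      "name": "cases.project.program.name",
      "kind": "enumerated",
      "allowed_values": ["TCGA", "CPTAC", "TARGET"],
      "label": "program"
    },
    {
      "name": "cases.project.project_id",
      "kind": "enumerated",
      "allowed_values": ["TCGA-LUAD", "TCGA-BRCA", "CPTAC-3", "TARGET-AML"],
      "label": "project"
    },
    {
      "name": "cases.demographic.gender",
      "kind": "enumerated",
      "allowed_values": ["female", "male"],
      "label": "gender"
    },
    {
      "name": "cases.primary_site",
      "kind": "enumerated",
      "allowed_values": ["breast", "bronchus and lung", "kidney"],
      "label": "primary site"
    },
    {
      "name": "cases.diagnoses.tissue_or_organ_of_origin",
      "kind": "enumerated",
      "allowed_values": ["lower lobe, lung", "middle lobe, lung", "upper lobe, lung"],
      "label": "tissue or organ of origin"
    },
    {
      "name": "cases.diagnoses.age_at_diagnosis",
      "kind": "numeric",
      "min_value": 0,
      "max_value": 32872,
      "units": "days",
      "label": "age at diagnosis"
    }
  ]
}
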