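{
  "description": "Lesion inventories of the 20-sample 30x leukemia-only validation set, encoded from each sample's WGS-revised karyotype and WGS additional findings, with the WGS subgroup labels printed for each sample (mapped to this package's rule vocabulary).",
  "samples": [
    {
      "sample_id": "P104",
      "chromosome_count": 55,
      "fusions": [],
      "cnas": [],
      "iamp21": false,
      "expected_labels": ["HeH"],
      "expected_primary": "HeH",
      "blasts_percent": 91
    },
    {
      "sample_id": "P109",
      "chromosome_count": 55,
      "fusions": [],
      "cnas": [
        {"locus": "IKZF1", "type": "deletion"},
        {"locus": "EBF1", "type": "deletion"}
      ],
      "iamp21": false,
      "expected_labels": ["HeH"],
      "expected_primary": "HeH",
      "blasts_percent": 67
    },
    {
      "sample_id": "P112",
      "chromosome_count": 52,
      "fusions": [],
      "cnas": [
        {"locus": "BTG1", "type": "deletion"},
        {"locus": "RB1", "type": "deletion"},
        {"locus": "EBF1", "type": "deletion"}
      ],
      "iamp21": false,
      "expected_labels": ["HeH"],
      "expected_primary": "HeH",
      "blasts_percent": 50
    },
    {
      "sample_id": "P116",
      "chromosome_count": 35,
      "fusions": [],
      "cnas": [],
      "iamp21": false,
      "expected_labels": ["HoL"],
      "expected_primary": "HoL",
      "blasts_percent": 78
    },
    {
      "sample_id": "P111",
      "chromosome_count": 46,
      "fusions": ["ETV6::RUNX1"],
      "cnas": [],
      "iamp21": false,
      "expected_labels": ["ETV6::RUNX1"],
      "expected_primary": "ETV6::RUNX1",
      "blasts_percent": 37
    },
    {
      "sample_id": "P113",
      "chromosome_count": 46,
      "fusions": ["ETV6::RUNX1", "PAX5::ZCCHC7"],
      "cnas": [],
      "iamp21": false,
      "expected_labels": ["ETV6::RUNX1"],
      "expected_primary": "ETV6::RUNX1",
      "blasts_percent": 81
    },
    {
      "sample_id": "P110",
      "chromosome_count": 46,
      "fusions": ["TCF3::PBX1"],
      "cnas": [],
      "iamp21": false,
      "expected_labels": ["TCF3::PBX1"],
      "expected_primary": "TCF3::PBX1",
      "blasts_percent": 90
    },
    {
      "sample_id": "P119",
      "chromosome_count": 46,
      "fusions": ["TCF3::PBX1"],
      "cnas": [],
      "iamp21": false,
      "expected_labels": ["TCF3::PBX1"],
      "expected_primary": "TCF3::PBX1",
      "blasts_percent": 90
    },
    {
      "sample_id": "P108",
      "chromosome_count": 46,
      "fusions": [],
      "cnas": [
        {"locus": "CDKN2A/B", "type": "deletion"},
        {"locus": "EBF1", "type": "deletion"},
        {"locus": "ETV6", "type": "deletion"},
        {"locus": "RB1", "type": "deletion", "biallelic": true}
      ],
      "iamp21": true,
      "expected_labels": ["iAMP21"],
      "expected_primary": "iAMP21",
      "blasts_percent": 85
    },
    {
      "sample_id": "P120",
      "chromosome_count": 46,
      "fusions": ["KMT2A::AFF1"],
      "cnas": [],
      "iamp21": false,
      "expected_labels": ["KMT2A-r"],
      "expected_primary": "KMT2A-r",
      "blasts_percent": 14
    },
    {
      "sample_id": "P118",
      "chromosome_count": 54,
      "fusions": ["BCR::ABL1"],
      "cnas": [],
      "iamp21": false,
      "expected_labels": ["Ph-positive"],
      "expected_primary": "Ph-positive",
      "blasts_percent": 90
    },
    {
      "sample_id": "P102",
      "chromosome_count": 46,
      "fusions": ["IGH::CRLF2", "PAX5::ZCCHC7"],
      "cnas": [
        {"locus": "IKZF1", "type": "deletion", "exons": "4-7"}
      ],
      "iamp21": false,
      "expected_labels": ["CRLF2-r", "PAX5-alt"],
      "expected_primary": "CRLF2-r",
      "blasts_percent": 90
    },
    {
      "sample_id": "P103",
      "chromosome_count": 45,
      "fusions": [],
      "cnas": [
        {"locus": "CDKN2A/B", "type": "deletion", "biallelic": true},
        {"locus": "IKZF1", "type": "deletion", "exons": "4-6"},
        {"locus": "PAX5", "type": "deletion"}
      ],
      "iamp21": false,
      "expected_labels": ["PAX5-alt"],
      "expected_primary": "PAX5-alt",
      "blasts_percent": 95
    },
    {
      "sample_id": "P105",
      "chromosome_count": 46,
      "fusions": ["ETV6::IKZF1"],
      "cnas": [
        {"locus": "CDKN2A/B", "type": "deletion"},
        {"locus": "PAX5", "type": "deletion", "exons": "2-6"}
      ],
      "iamp21": false,
      "expected_labels": ["ETV6::RUNX1-like"],
      "expected_primary": "ETV6::RUNX1-like",
      "blasts_percent": 93
    },
    {
      "sample_id": "P106",
      "chromosome_count": 46,
      "fusions": ["TAF15::ZNF384"],
      "cnas": [
        {"locus": "IKZF1", "type": "deletion", "exons": "2-6"}
      ],
      "iamp21": false,
      "expected_labels": ["ZNF384-r"],
      "expected_primary": "ZNF384-r",
      "blasts_percent": 88
    },
    {
      "sample_id": "P107",
      "chromosome_count": 45,
      "fusions": ["PAX5::SNTA1", "PAX5::ARHGAP22"],
      "cnas": [
        {"locus": "CDKN2A/B", "type": "deletion", "biallelic": true}
      ],
      "iamp21": false,
      "expected_labels": ["PAX5-alt"],
      "expected_primary": "PAX5-alt",
      "blasts_percent": 86
    },
    {
      "sample_id": "P114",
      "chromosome_count": 46,
      "fusions": [],
      "cnas": [
        {"locus": "ERG", "type": "deletion"}
      ],
      "iamp21": false,
      "expected_labels": [],
      "expected_primary": null,
      "targeted_support_pairs": 34,
      "blasts_percent": 75
    },
    {
      "sample_id": "P115",
      "chromosome_count": 46,
      "fusions": ["KMT2C::IKZF1"],
      "cnas": [
        {"locus": "PAX5", "type": "deletion"},
        {"locus": "ETV6", "type": "deletion"},
        {"locus": "EBF1", "type": "deletion"}
      ],
      "iamp21": false,
      "expected_labels": ["ETV6::RUNX1-like", "PAX5-alt"],
      "expected_primary": "ETV6::RUNX1-like",
      "blasts_percent": 90
    },
    {
      "sample_id": "P117",
      "chromosome_count": 46,
      "fusions": [],
      "cnas": [
        {"locus": "CDKN2A/B", "type": "deletion", "biallelic": true},
        {"locus": "PAX5", "type": "deletion"}
      ],
      "iamp21": false,
      "expected_labels": ["PAX5-alt"],
      "expected_primary": "PAX5-alt",
      "blasts_percent": 90
    },
    {
      "sample_id": "P121",
      "chromosome_count": 45,
      "fusions": ["PAX5::NOL4L"],
      "cnas": [
        {"locus": "CDKN2A/B", "type": "deletion", "biallelic": true},
        {"locus": "PAX5", "type": "deletion", "exons": "6-10"},
        {"locus": "IKZF1", "type": "deletion", "exons": "4-7"}
      ],
      "iamp21": false,
      "expected_labels": ["PAX5-alt"],
      "expected_primary": "PAX5-alt",
      "blasts_percent": 98
    }
  ]
}
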