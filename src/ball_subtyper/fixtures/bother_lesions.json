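{
  "description": "The CRLF2-rearranged B-other lesion inventory: three samples with an IGH-to-CRLF2 translocation (each co-occurring with a PAX5 rearrangement) and seven with a P2RY8::CRLF2 fusion, of which three (Down-syndrome ALL) carry it as the only detected lesion.",
  "samples": [
    {"sample_id": "B01", "fusions": ["IGH::CRLF2", "PAX5::ZCCHC7"], "cnas": []},
    {"sample_id": "B02", "fusions": ["IGH::CRLF2", "PAX5::NOL4L"], "cnas": []},
    {"sample_id": "B03", "fusions": ["IGH::CRLF2"], "cnas": [{"locus": "PAX5", "type": "deletion"}]},
    {"sample_id": "B04", "fusions": ["P2RY8::CRLF2"], "cnas": [{"locus": "PAX5", "type": "deletion"}]},
    {"sample_id": "B05", "fusions": ["P2RY8::CRLF2"], "cnas": [{"locus": "PAX5", "type": "deletion"}]},
    {"sample_id": "B06", "fusions": ["P2RY8::CRLF2", "PAX5::ZCCHC7"], "cnas": []},
    {"sample_id": "B07", "fusions": ["P2RY8::CRLF2"], "cnas": [{"locus": "PAX5", "type": "amplification"}]},
    {"sample_id": "B08", "fusions": ["P2RY8::CRLF2"], "cnas": [], "ds_all": true},
    {"sample_id": "B09", "fusions": ["P2RY8::CRLF2"], "cnas": [], "ds_all": true},
    {"sample_id": "B10", "fusions": ["P2RY8::CRLF2"], "cnas": [], "ds_all": true}
  ]
}
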