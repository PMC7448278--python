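{
  "precursor_name": "[13C6]anthranilate",
  "labels": [
    {"element": "C", "isotope": "13C", "n_labeled": 6, "n_retained": 6}
  ],
  "retention_note": "All six labeled ring carbons of anthranilate are carried intact into the product as the anthraniloyl unit; expected nominal shift +6 Da."
}
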