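{
  "precursor_name": "L-tryptophan-D5 (indole-ring pentadeuterated)",
  "labels": [
    {"element": "H", "isotope": "2H", "n_labeled": 5, "n_retained": 4}
  ],
  "retention_note": "Indoleamine 2,3-dioxygenase cleaves the indole 2,3-bond, turning tryptophan into N-formyl-kynurenine; the indole C2 position becomes the formyl carbon, and its deuteron is lost on deformylation to kynurenine before incorporation. Four of five ring labels survive; expected nominal shift +4 Da instead of +5."
}
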