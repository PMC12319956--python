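{
  "name": "AFID32",
  "description": "Protocol registry for the 32 anatomical fiducials. Labels and ids are normative; descriptions are editable display text.",
  "afids": [
    {"afid_id": 1, "label": "AC", "description": "anterior commissure"},
    {"afid_id": 2, "label": "PC", "description": "posterior commissure"},
    {"afid_id": 3, "label": "ICS", "description": "infracollicular sulcus"},
    {"afid_id": 4, "label": "PMJ", "description": "pontomedullary junction"},
    {"afid_id": 5, "label": "SIPF", "description": "superior interpeduncular fossa"},
    {"afid_id": 6, "label": "RSLMS", "description": "right superior lateral mesencephalic sulcus"},
    {"afid_id": 7, "label": "LSLMS", "description": "left superior lateral mesencephalic sulcus"},
    {"afid_id": 8, "label": "RILMS", "description": "right inferior lateral mesencephalic sulcus"},
    {"afid_id": 9, "label": "LILMS", "description": "left inferior lateral mesencephalic sulcus"},
    {"afid_id": 10, "label": "CUL", "description": "culmen"},
    {"afid_id": 11, "label": "IMS", "description": "intermammillary sulcus"},
    {"afid_id": 12, "label": "RMB", "description": "right mammillary body"},
    {"afid_id": 13, "label": "LMB", "description": "left mammillary body"},
    {"afid_id": 14, "label": "PG", "description": "pineal gland"},
    {"afid_id": 15, "label": "RLVAC", "description": "right lateral aspect of frontal horn at AC"},
    {"afid_id": 16, "label": "LLVAC", "description": "left lateral aspect of frontal horn at AC"},
    {"afid_id": 17, "label": "RLVPC", "description": "right lateral aspect of frontal horn at PC"},
    {"afid_id": 18, "label": "LLVPC", "description": "left lateral aspect of frontal horn at PC"},
    {"afid_id": 19, "label": "GENU", "description": "genu of corpus callosum"},
    {"afid_id": 20, "label": "SPL", "description": "splenium of corpus callosum"},
    {"afid_id": 21, "label": "RALTH", "description": "right anterolateral temporal horn"},
    {"afid_id": 22, "label": "LALTH", "description": "left anterolateral temporal horn"},
    {"afid_id": 23, "label": "RSAMTH", "description": "right superior anteromedial temporal horn"},
    {"afid_id": 24, "label": "LSAMTH", "description": "left superior anteromedial temporal horn"},
    {"afid_id": 25, "label": "RIAMTH", "description": "right inferior anteromedial temporal horn"},
    {"afid_id": 26, "label": "LIAMTH", "description": "left inferior anteromedial temporal horn"},
    {"afid_id": 27, "label": "RIGO", "description": "right indusium griseum origin"},
    {"afid_id": 28, "label": "LIGO", "description": "left indusium griseum origin"},
    {"afid_id": 29, "label": "RVOH", "description": "right ventral occipital horn"},
    {"afid_id": 30, "label": "LVOH", "description": "left ventral occipital horn"},
    {"afid_id": 31, "label": "ROSF", "description": "right olfactory sulcal fundus"},
    {"afid_id": 32, "label": "LOSF", "description": "left olfactory sulcal fundus"}
  ]
}
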