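{
  "type": "object",
  "required": [
    "config_hash",
    "seed",
    "n_subjects",
    "n_electrodes",
    "stages",
    "global_afre",
    "rmse_by_axis",
    "stacked_pca",
    "attribution",
    "vta",
    "outputs",
    "versions"
  ],
  "properties": {
    "config_hash": {"type": "string"},
    "seed": {"type": ["integer", "null"]},
    "n_subjects": {"type": "integer"},
    "n_electrodes": {"type": "integer"},
    "stages": {"type": "array", "items": {"type": "string"}},
    "global_afre": {
      "type": "object",
      "required": ["median", "iqr_low", "iqr_high", "n"],
      "properties": {
        "median": {"type": "number"},
        "iqr_low": {"type": "number"},
        "iqr_high": {"type": "number"},
        "n": {"type": "integer"}
      }
    },
    "rmse_by_axis": {
      "type": "object",
      "required": ["x", "y", "z"],
      "properties": {
        "x": {"type": "number"},
        "y": {"type": "number"},
        "z": {"type": "number"}
      }
    },
    "stacked_pca": {
      "type": "object",
      "required": ["skipped"],
      "properties": {
        "skipped": {"type": "boolean"},
        "reason": {"type": ["string", "null"]},
        "explained_fraction": {"type": "array", "items": {"type": "number"}},
        "landmarks": {"type": "array", "items": {"type": "integer"}}
      }
    },
    "attribution": {
      "type": "object",
      "required": ["skipped"],
      "properties": {
        "skipped": {"type": "boolean"},
        "reason": {"type": ["string", "null"]},
        "r2_prc1": {"type": "number"},
        "p_prc1": {"type": "number"},
        "explained_mm_median": {"type": "number"},
        "explained_mm_min": {"type": "number"},
        "explained_mm_max": {"type": "number"}
      }
    },
    "vta": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["volume_mm3", "shift_mm", "radius_mm", "dice"],
        "properties": {
          "volume_mm3": {"type": "number"},
          "shift_mm": {"type": "number"},
          "radius_mm": {"type": "number"},
          "dice": {"type": "number"}
        }
      }
    },
    "outputs": {"type": "object"},
    "versions": {"type": "object"}
  }
}
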