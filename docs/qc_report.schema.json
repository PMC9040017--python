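{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "atacqc QC report",
  "description": "Schema (version 1.0) of the JSON report written by run_qc. Unknown additional fields are preserved on round-trip. All numerics are finite.",
  "type": "object",
  "required": ["schema_version", "parameters", "alignment", "metrics"],
  "properties": {
    "schema_version": {"const": "1.0"},
    "parameters": {
      "type": "object",
      "description": "Every RunConfig field actually used, for provenance (shift, ext, n_background_regions, width, rpkm_threshold, suben depth/pseudo, saturation step, promoter half-window, padj/log2FC thresholds, normalize_to, mapq_min, seed, paths)."
    },
    "alignment": {
      "type": "object",
      "required": ["n_unique_nonredundant", "duplication_rate",
                   "per_chrom_counts", "mito_rate", "tally"],
      "properties": {
        "n_unique_nonredundant": {"type": "integer", "minimum": 0},
        "duplication_rate": {"type": "number", "minimum": 0, "maximum": 1},
        "per_chrom_counts": {"type": "object",
                             "additionalProperties": {"type": "integer"}},
        "mito_rate": {"type": "number", "minimum": 0, "maximum": 1},
        "tally": {"type": "object"}
      }
    },
    "metrics": {
      "type": "object",
      "properties": {
        "e_total": {"type": "integer", "minimum": 0},
        "rupr": {"type": "number", "minimum": 0, "maximum": 1},
        "background": {
          "type": "object",
          "required": ["n_regions", "region_width", "rpkm_threshold",
                       "n_high", "background", "seed"]
        },
        "proen": {"type": ["number", "null"]},
        "suben": {
          "type": "object",
          "required": ["sample_depth", "pseudo", "e_sampled",
                       "e_under_peaks", "peak_length", "suben", "form"]
        },
        "saturation": {
          "type": ["array", "null"],
          "items": {"type": "array",
                    "prefixItems": [{"type": "number"}, {"type": "number"}]}
        },
        "signal_ranking": {"type": ["array", "null"],
                           "items": {"type": "number"}},
        "promoter_peak_fraction": {"type": ["number", "null"]}
      }
    },
    "grades": {
      "type": "object",
      "additionalProperties": {"enum": ["good", "acceptable", "fail", "ungraded"]}
    },
    "validation": {
      "type": ["object", "null"],
      "required": ["n_peaks", "n_reference", "n_validated", "n_unvalidated",
                   "fdr_like", "n_missed", "fnr_like"]
    },
    "notes": {"type": "object"}
  }
}
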