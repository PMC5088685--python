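{
  "$defs": {
    "ExpressionOutlierReport": {
      "additionalProperties": false,
      "properties": {
        "flag": {
          "title": "Flag",
          "type": "string"
        },
        "gene": {
          "title": "Gene",
          "type": "string"
        },
        "normalized": {
          "title": "Normalized",
          "type": "number"
        },
        "percentile": {
          "title": "Percentile",
          "type": "number"
        },
        "rank": {
          "title": "Rank",
          "type": "number"
        },
        "z": {
          "anyOf": [
            {
              "type": "number"
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "Z"
        }
      },
      "required": [
        "gene",
        "normalized",
        "rank",
        "percentile",
        "flag"
      ],
      "title": "ExpressionOutlierReport",
      "type": "object"
    },
    "GermlineFinding": {
      "additionalProperties": false,
      "properties": {
        "alt": {
          "title": "Alt",
          "type": "string"
        },
        "chrom": {
          "title": "Chrom",
          "type": "string"
        },
        "consequence": {
          "title": "Consequence",
          "type": "string"
        },
        "gene": {
          "title": "Gene",
          "type": "string"
        },
        "normal_af": {
          "anyOf": [
            {
              "type": "number"
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "Normal Af"
        },
        "population_af": {
          "anyOf": [
            {
              "type": "number"
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "Population Af"
        },
        "pos": {
          "title": "Pos",
          "type": "integer"
        },
        "ref": {
          "title": "Ref",
          "type": "string"
        },
        "report_bucket": {
          "title": "Report Bucket",
          "type": "string"
        }
      },
      "required": [
        "chrom",
        "pos",
        "ref",
        "alt",
        "gene",
        "consequence",
        "report_bucket"
      ],
      "title": "GermlineFinding",
      "type": "object"
    },
    "Provenance": {
      "additionalProperties": false,
      "properties": {
        "config": {
          "additionalProperties": true,
          "title": "Config",
          "type": "object"
        },
        "seeds": {
          "additionalProperties": {
            "type": "integer"
          },
          "title": "Seeds",
          "type": "object"
        },
        "timestamp": {
          "title": "Timestamp",
          "type": "string"
        },
        "version": {
          "title": "Version",
          "type": "string"
        }
      },
      "required": [
        "config",
        "seeds",
        "version",
        "timestamp"
      ],
      "title": "Provenance",
      "type": "object"
    },
    "SegmentReport": {
      "additionalProperties": false,
      "properties": {
        "chrom": {
          "title": "Chrom",
          "type": "string"
        },
        "end": {
          "title": "End",
          "type": "integer"
        },
        "mean_statistic": {
          "title": "Mean Statistic",
          "type": "number"
        },
        "n_features": {
          "title": "N Features",
          "type": "integer"
        },
        "segment_class": {
          "title": "Segment Class",
          "type": "string"
        },
        "start": {
          "title": "Start",
          "type": "integer"
        }
      },
      "required": [
        "chrom",
        "start",
        "end",
        "segment_class",
        "mean_statistic",
        "n_features"
      ],
      "title": "SegmentReport",
      "type": "object"
    },
    "SomaticFinding": {
      "additionalProperties": false,
      "properties": {
        "alt": {
          "title": "Alt",
          "type": "string"
        },
        "chrom": {
          "title": "Chrom",
          "type": "string"
        },
        "consequence": {
          "title": "Consequence",
          "type": "string"
        },
        "expression_flag": {
          "anyOf": [
            {
              "type": "string"
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "Expression Flag"
        },
        "flags": {
          "items": {
            "type": "string"
          },
          "title": "Flags",
          "type": "array"
        },
        "gene": {
          "title": "Gene",
          "type": "string"
        },
        "loh_segment_class": {
          "anyOf": [
            {
              "type": "string"
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "Loh Segment Class"
        },
        "normal_af": {
          "title": "Normal Af",
          "type": "number"
        },
        "pos": {
          "title": "Pos",
          "type": "integer"
        },
        "ref": {
          "title": "Ref",
          "type": "string"
        },
        "tumor_af": {
          "title": "Tumor Af",
          "type": "number"
        }
      },
      "required": [
        "chrom",
        "pos",
        "ref",
        "alt",
        "gene",
        "consequence",
        "tumor_af",
        "normal_af"
      ],
      "title": "SomaticFinding",
      "type": "object"
    },
    "TissueAssignment": {
      "additionalProperties": false,
      "properties": {
        "label": {
          "title": "Label",
          "type": "string"
        },
        "per_label_similarity": {
          "additionalProperties": {
            "type": "number"
          },
          "title": "Per Label Similarity",
          "type": "object"
        },
        "vote_fraction": {
          "title": "Vote Fraction",
          "type": "number"
        }
      },
      "required": [
        "label",
        "vote_fraction",
        "per_label_similarity"
      ],
      "title": "TissueAssignment",
      "type": "object"
    }
  },
  "additionalProperties": false,
  "description": "Machine-readable multi-evidence case summary.",
  "properties": {
    "cnv_segments": {
      "items": {
        "$ref": "#/$defs/SegmentReport"
      },
      "title": "Cnv Segments",
      "type": "array"
    },
    "expression_outliers": {
      "items": {
        "$ref": "#/$defs/ExpressionOutlierReport"
      },
      "title": "Expression Outliers",
      "type": "array"
    },
    "germline_findings": {
      "items": {
        "$ref": "#/$defs/GermlineFinding"
      },
      "title": "Germline Findings",
      "type": "array"
    },
    "loh_segments": {
      "items": {
        "$ref": "#/$defs/SegmentReport"
      },
      "title": "Loh Segments",
      "type": "array"
    },
    "provenance": {
      "$ref": "#/$defs/Provenance"
    },
    "somatic_findings": {
      "items": {
        "$ref": "#/$defs/SomaticFinding"
      },
      "title": "Somatic Findings",
      "type": "array"
    },
    "tissue_assignment": {
      "anyOf": [
        {
          "$ref": "#/$defs/TissueAssignment"
        },
        {
          "type": "null"
        }
      ],
      "default": null
    }
  },
  "required": [
    "germline_findings",
    "somatic_findings",
    "cnv_segments",
    "loh_segments",
    "expression_outliers",
    "provenance"
  ],
  "title": "CaseReport",
  "type": "object"
}
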