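{
  "$id": "https://innomap.invalid/schemas/arsenal.v1.json",
  "$schema": "http://json-schema.org/draft-07/schema#",
  "additionalProperties": false,
  "properties": {
    "indication": {
      "additionalProperties": false,
      "properties": {
        "coadministration_terms": {
          "items": {
            "type": "string"
          },
          "type": "array"
        },
        "condition_term": {
          "type": "string"
        },
        "target_kind": {
          "enum": [
            "disease",
            "symptom",
            "risk_factor"
          ],
          "type": "string"
        },
        "treatment_type": {
          "enum": [
            "curative",
            "symptomatic",
            "substitutive",
            "preventive"
          ],
          "type": "string"
        }
      },
      "required": [
        "condition_term",
        "target_kind",
        "treatment_type"
      ],
      "type": "object"
    },
    "known_molecule_registry": {
      "items": {
        "type": "string"
      },
      "type": "array"
    },
    "members": {
      "items": {
        "$id": "https://innomap.invalid/schemas/product.v1.json",
        "$schema": "http://json-schema.org/draft-07/schema#",
        "additionalProperties": false,
        "properties": {
          "brand_name": {
            "type": "string"
          },
          "contraindication_terms": {
            "items": {
              "type": "string"
            },
            "type": "array"
          },
          "convenience_grade": {
            "enum": [
              "low",
              "medium",
              "high",
              "unknown"
            ],
            "type": "string"
          },
          "dose_adjustability_grade": {
            "enum": [
              "easy",
              "moderate",
              "difficult",
              "unknown"
            ],
            "type": "string"
          },
          "dosing": {
            "additionalProperties": true,
            "properties": {
              "dose_per_intake_unit": {
                "type": [
                  "string",
                  "null"
                ]
              },
              "dose_per_intake_value": {
                "minimum": 0,
                "type": [
                  "number",
                  "null"
                ]
              },
              "intakes_per_day": {
                "exclusiveMinimum": 0,
                "type": [
                  "number",
                  "null"
                ]
              },
              "units_per_intake": {
                "exclusiveMinimum": 0,
                "type": [
                  "integer",
                  "null"
                ]
              }
            },
            "type": "object"
          },
          "indications": {
            "items": {
              "additionalProperties": false,
              "properties": {
                "coadministration_terms": {
                  "items": {
                    "type": "string"
                  },
                  "type": "array"
                },
                "condition_term": {
                  "type": "string"
                },
                "target_kind": {
                  "enum": [
                    "disease",
                    "symptom",
                    "risk_factor"
                  ],
                  "type": "string"
                },
                "treatment_type": {
                  "enum": [
                    "curative",
                    "symptomatic",
                    "substitutive",
                    "preventive"
                  ],
                  "type": "string"
                }
              },
              "required": [
                "condition_term",
                "target_kind",
                "treatment_type"
              ],
              "type": "object"
            },
            "minItems": 1,
            "type": "array"
          },
          "invasiveness_grade": {
            "enum": [
              "noninvasive",
              "minimally_invasive",
              "invasive",
              "unknown"
            ],
            "type": "string"
          },
          "mechanism_term": {
            "type": "string"
          },
          "monitoring_test_terms": {
            "items": {
              "type": "string"
            },
            "type": "array"
          },
          "overdose": {
            "additionalProperties": false,
            "properties": {
              "antidote_available": {
                "enum": [
                  "yes",
                  "no",
                  "unknown"
                ],
                "type": "string"
              },
              "risk_grade": {
                "enum": [
                  "low",
                  "moderate",
                  "high",
                  "unknown"
                ],
                "type": "string"
              }
            },
            "type": "object"
          },
          "pharmaceutical_form": {
            "type": "string"
          },
          "pharmacotherapeutic_group": {
            "type": "string"
          },
          "presentation_term": {
            "type": "string"
          },
          "routes": {
            "items": {
              "type": "string"
            },
            "minItems": 1,
            "type": "array"
          },
          "serious_adr_terms": {
            "items": {
              "type": "string"
            },
            "type": "array"
          },
          "serious_ddi_terms": {
            "items": {
              "type": "string"
            },
            "type": "array"
          },
          "substances": {
            "items": {
              "additionalProperties": false,
              "properties": {
                "atc_code": {
                  "type": [
                    "string",
                    "null"
                  ]
                },
                "inn_name": {
                  "type": "string"
                },
                "strength_unit": {
                  "type": [
                    "string",
                    "null"
                  ]
                },
                "strength_value": {
                  "minimum": 0,
                  "type": [
                    "number",
                    "null"
                  ]
                }
              },
              "required": [
                "inn_name"
              ],
              "type": "object"
            },
            "minItems": 1,
            "type": "array"
          }
        },
        "required": [
          "brand_name",
          "substances",
          "pharmaceutical_form",
          "routes",
          "presentation_term",
          "pharmacotherapeutic_group",
          "mechanism_term",
          "indications"
        ],
        "title": "ProductRecord (v1)",
        "type": "object"
      },
      "type": "array"
    }
  },
  "required": [
    "indication",
    "members",
    "known_molecule_registry"
  ],
  "title": "TherapeuticArsenal (v1)",
  "type": "object"
}
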