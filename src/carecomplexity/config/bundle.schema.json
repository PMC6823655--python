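{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "$id": "carecomplexity/bundle/v1",
  "title": "Multi-source client record bundle",
  "type": "object",
  "additionalProperties": false,
  "properties": {
    "schema_version": {"type": "string"},
    "encounters": {
      "type": "array",
      "items": {
        "type": "object",
        "additionalProperties": false,
        "required": ["client_id", "date"],
        "properties": {
          "client_id": {"type": "string", "minLength": 1},
          "date": {"type": "string", "format": "date"},
          "source_system": {"type": "string"},
          "program": {"type": "string"},
          "booked": {"type": "boolean"},
          "attended": {"type": "boolean"}
        }
      }
    },
    "honos": {
      "type": "array",
      "items": {
        "type": "object",
        "additionalProperties": false,
        "required": ["client_id", "date", "items"],
        "properties": {
          "client_id": {"type": "string", "minLength": 1},
          "date": {"type": "string", "format": "date"},
          "items": {
            "type": "array",
            "minItems": 12,
            "maxItems": 12,
            "items": {"type": "integer", "minimum": 0, "maximum": 4}
          }
        }
      }
    },
    "problems": {
      "type": "array",
      "items": {
        "type": "object",
        "additionalProperties": false,
        "required": ["client_id", "code"],
        "properties": {
          "client_id": {"type": "string", "minLength": 1},
          "code": {"type": "string", "minLength": 1},
          "label": {"type": "string"},
          "is_sumh": {"type": "boolean"},
          "is_complex_care": {"type": "boolean"},
          "is_neurodegenerative": {"type": "boolean"}
        }
      }
    },
    "vitals": {
      "type": "array",
      "items": {
        "type": "object",
        "additionalProperties": false,
        "required": ["client_id", "date"],
        "properties": {
          "client_id": {"type": "string", "minLength": 1},
          "date": {"type": "string", "format": "date"},
          "systolic_bp": {"type": ["number", "null"], "exclusiveMinimum": 0},
          "diastolic_bp": {"type": ["number", "null"], "exclusiveMinimum": 0},
          "bmi": {"type": ["number", "null"], "exclusiveMinimum": 0}
        }
      }
    },
    "ed_visits": {
      "type": "array",
      "items": {
        "type": "object",
        "additionalProperties": false,
        "required": ["client_id", "date", "ctas_level"],
        "properties": {
          "client_id": {"type": "string", "minLength": 1},
          "date": {"type": "string", "format": "date"},
          "ctas_level": {"type": "integer", "minimum": 1, "maximum": 5}
        }
      }
    },
    "admissions": {
      "type": "array",
      "items": {
        "type": "object",
        "additionalProperties": false,
        "required": ["client_id", "admit_date"],
        "properties": {
          "client_id": {"type": "string", "minLength": 1},
          "admit_date": {"type": "string", "format": "date"},
          "discharge_date": {"type": ["string", "null"], "format": "date"}
        }
      }
    },
    "flags": {
      "type": "array",
      "items": {
        "type": "object",
        "additionalProperties": false,
        "required": ["client_id", "flag_kind"],
        "properties": {
          "client_id": {"type": "string", "minLength": 1},
          "flag_kind": {
            "type": "string",
            "enum": ["PWD_FORM", "SHX_CODE", "INTERRAI_MDS", "MOBILITY_ASSESSMENT", "VIOLENCE_ALERT", "EXTENDED_LEAVE"]
          },
          "date": {"type": ["string", "null"], "format": "date"}
        }
      }
    },
    "phq9": {
      "type": "array",
      "items": {
        "type": "object",
        "additionalProperties": false,
        "required": ["client_id", "date", "total"],
        "properties": {
          "client_id": {"type": "string", "minLength": 1},
          "date": {"type": "string", "format": "date"},
          "total": {"type": "integer", "minimum": 0, "maximum": 27}
        }
      }
    }
  }
}
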