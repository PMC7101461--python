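{
  "$defs": {
    "Provenance": {
      "properties": {
        "package": {
          "title": "Package",
          "type": "string"
        },
        "version": {
          "title": "Version",
          "type": "string"
        },
        "seed": {
          "title": "Seed",
          "type": "integer"
        },
        "input_digests": {
          "additionalProperties": {
            "type": "string"
          },
          "title": "Input Digests",
          "type": "object"
        }
      },
      "required": [
        "package",
        "version",
        "seed",
        "input_digests"
      ],
      "title": "Provenance",
      "type": "object"
    },
    "StageEffects": {
      "properties": {
        "per_run_average": {
          "items": {
            "type": "number"
          },
          "title": "Per Run Average",
          "type": "array"
        },
        "per_run_difference": {
          "items": {
            "type": "number"
          },
          "title": "Per Run Difference",
          "type": "array"
        },
        "effects": {
          "additionalProperties": {
            "type": "number"
          },
          "title": "Effects",
          "type": "object"
        },
        "change_in_mean": {
          "title": "Change In Mean",
          "type": "number"
        },
        "s": {
          "title": "S",
          "type": "number"
        },
        "n_cycles": {
          "title": "N Cycles",
          "type": "integer"
        },
        "error_limits": {
          "additionalProperties": {
            "type": "number"
          },
          "title": "Error Limits",
          "type": "object"
        },
        "decision": {
          "additionalProperties": true,
          "title": "Decision",
          "type": "object"
        }
      },
      "required": [
        "per_run_average",
        "per_run_difference",
        "effects",
        "change_in_mean",
        "s",
        "n_cycles",
        "error_limits",
        "decision"
      ],
      "title": "StageEffects",
      "type": "object"
    },
    "StageFit": {
      "properties": {
        "model": {
          "title": "Model",
          "type": "string"
        },
        "coefficients": {
          "anyOf": [
            {
              "items": {
                "type": "number"
              },
              "type": "array"
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "Coefficients"
        },
        "r2_overall": {
          "anyOf": [
            {
              "type": "number"
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "R2 Overall"
        },
        "restart_index": {
          "anyOf": [
            {
              "type": "integer"
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "Restart Index"
        },
        "final_mse": {
          "anyOf": [
            {
              "type": "number"
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "Final Mse"
        }
      },
      "required": [
        "model"
      ],
      "title": "StageFit",
      "type": "object"
    },
    "StageOptimize": {
      "properties": {
        "grid_size": {
          "title": "Grid Size",
          "type": "integer"
        },
        "argmax": {
          "additionalProperties": {
            "type": "number"
          },
          "title": "Argmax",
          "type": "object"
        },
        "top_window": {
          "items": {
            "additionalProperties": {
              "type": "number"
            },
            "type": "object"
          },
          "title": "Top Window",
          "type": "array"
        }
      },
      "required": [
        "grid_size",
        "argmax",
        "top_window"
      ],
      "title": "StageOptimize",
      "type": "object"
    }
  },
  "additionalProperties": false,
  "description": "Schema of the pipeline's single JSON output.",
  "properties": {
    "provenance": {
      "$ref": "#/$defs/Provenance"
    },
    "evop": {
      "$ref": "#/$defs/StageEffects"
    },
    "fit": {
      "$ref": "#/$defs/StageFit"
    },
    "optimize": {
      "$ref": "#/$defs/StageOptimize"
    }
  },
  "required": [
    "provenance",
    "evop",
    "fit",
    "optimize"
  ],
  "title": "Bundle",
  "type": "object"
}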