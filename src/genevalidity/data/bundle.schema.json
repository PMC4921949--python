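{
  "$schema": "http://json-schema.org/draft-07/schema#",
  "$id": "https://example.org/genevalidity/bundle.schema.json",
  "title": "Evidence bundle",
  "description": "Structured evidence store for gene-condition clinical validity curation. The genevalidity loader enforces these constraints natively; this schema documents the on-disk dialect for other tools.",
  "type": "object",
  "additionalProperties": false,
  "properties": {
    "genes": {"type": "array", "items": {"$ref": "#/definitions/gene"}},
    "conditions": {"type": "array", "items": {"$ref": "#/definitions/condition"}},
    "variants": {"type": "array", "items": {"$ref": "#/definitions/variant"}},
    "cases": {"type": "array", "items": {"$ref": "#/definitions/case"}},
    "segregations": {"type": "array", "items": {"$ref": "#/definitions/segregation"}},
    "functionals": {"type": "array", "items": {"$ref": "#/definitions/functional"}},
    "populations": {"type": "array", "items": {"$ref": "#/definitions/population"}}
  },
  "definitions": {
    "gene": {
      "type": "object",
      "required": ["symbol"],
      "additionalProperties": false,
      "properties": {
        "symbol": {"type": "string", "pattern": "^[A-Z][A-Z0-9-]*$"},
        "aliases": {"type": "array", "items": {"type": "string"}},
        "preliminary_links": {
          "type": "array",
          "items": {
            "type": "array",
            "minItems": 2,
            "maxItems": 2,
            "items": [
              {"type": "string"},
              {"enum": ["case_series_vus_only", "linkage_only", "functional_only", "animal_only"]}
            ]
          }
        }
      }
    },
    "condition": {
      "type": "object",
      "required": ["id", "name"],
      "additionalProperties": false,
      "properties": {
        "id": {"type": "string", "minLength": 1},
        "name": {"type": "string"},
        "inheritance": {"type": "array", "items": {"enum": ["AD", "AR", "XL"]}},
        "is_syndromic": {"type": "boolean"},
        "is_generic": {"type": "boolean"},
        "features": {"type": "array", "items": {"type": "string"}}
      }
    },
    "variant": {
      "type": "object",
      "required": ["id", "gene", "hgvs", "consequence"],
      "additionalProperties": false,
      "properties": {
        "id": {"type": "string", "minLength": 1},
        "gene": {"type": "string", "minLength": 1},
        "hgvs": {"type": "string", "pattern": "^[cpgmn]\\.\\S+$"},
        "consequence": {"enum": ["missense", "nonsense", "frameshift", "splice", "exonic_deletion", "synonymous", "other"]},
        "computational_support": {"type": "boolean"}
      }
    },
    "case": {
      "type": "object",
      "required": ["id", "variant", "proband", "family", "condition"],
      "additionalProperties": false,
      "properties": {
        "id": {"type": "string", "minLength": 1},
        "variant": {"type": "string", "minLength": 1},
        "proband": {"type": "string", "minLength": 1},
        "family": {"type": "string", "minLength": 1},
        "condition": {"type": "string", "minLength": 1},
        "phenotype_features": {"type": "array", "items": {"type": "string"}},
        "severity": {"enum": ["mild", "classic", "severe"]},
        "onset": {"enum": ["infantile", "childhood", "adult"]},
        "de_novo": {"enum": ["none", "assumed", "confirmed_parentage"]},
        "zygosity": {"enum": ["het", "hom", "compound_het"]}
      }
    },
    "segregation": {
      "type": "object",
      "required": ["id", "variant", "family", "lod", "affected_condition"],
      "additionalProperties": false,
      "properties": {
        "id": {"type": "string", "minLength": 1},
        "variant": {"type": "string", "minLength": 1},
        "family": {"type": "string", "minLength": 1},
        "lod": {"type": "number"},
        "affected_condition": {"type": "string", "minLength": 1},
        "family_count": {"type": "integer", "minimum": 1}
      }
    },
    "functional": {
      "type": "object",
      "required": ["id", "variant", "assay", "effect"],
      "additionalProperties": false,
      "properties": {
        "id": {"type": "string", "minLength": 1},
        "variant": {"type": "string", "minLength": 1},
        "assay": {"enum": ["biochemical", "cellular", "animal_model"]},
        "effect": {"enum": ["loss_of_function", "gain_of_function", "no_effect"]},
        "mechanism_concordant": {"type": "boolean"}
      }
    },
    "population": {
      "type": "object",
      "required": ["id", "variant", "cohort", "allele_count", "allele_number"],
      "additionalProperties": false,
      "properties": {
        "id": {"type": "string", "minLength": 1},
        "variant": {"type": "string", "minLength": 1},
        "cohort": {"type": "string", "minLength": 1},
        "allele_count": {"type": "integer", "minimum": 0},
        "allele_number": {"type": "integer", "minimum": 1}
      }
    }
  }
}
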