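"""Bundle serialization: JSON on disk, dataclasses in memory.

The on-disk dialect is a single UTF-8 JSON object with the top-level keys
``genes, conditions, variants, cases, segregations, functionals,
populations`` (all optional; an empty object is the empty bundle). A JSON
Schema describing the dialect ships with the package
(``data/bundle.schema.json``); the loader enforces the same constraints
directly, so the schema file is interoperability documentation.

Round-trip guarantee: ``load_bundle(p)`` after ``write_bundle(b, p)`` is
structurally equal to ``b``.
"""

from __future__ import annotations

import json
from pathlib import Path

from .evidence import (
    BundleValidationError,
    CaseObservation,
    ConditionRecord,
    EvidenceBundle,
    FunctionalDatum,
    GeneRecord,
    PopulationDatum,
    SegregationDatum,
    VariantRecord,
)

__all__ = ["load_bundle", "write_bundle", "bundle_to_dict", "bundle_from_dict"]

_COLLECTIONS = (
    "genes", "conditions", "variants", "cases",
    "segregations", "functionals", "populations",
)


def bundle_to_dict(bundle: EvidenceBundle) -> dict:
    return {
        "genes": [
            {
                "symbol": g.symbol,
                "aliases": list(g.aliases),
                "preliminary_links": [list(link) for link in g.preliminary_links],
            }
            for g in bundle.genes
        ],
        "conditions": [
            {
                "id": c.id,
                "name": c.name,
                "inheritance": sorted(c.inheritance),
                "is_syndromic": c.is_syndromic,
                "is_generic": c.is_generic,
                "features": list(c.features),
            }
            for c in bundle.conditions
        ],
        "variants": [
            {
                "id": v.id,
                "gene": v.gene,
                "hgvs": v.hgvs,
                "consequence": v.consequence,
                "computational_support": v.computational_support,
            }
            for v in bundle.variants
        ],
        "cases": [
            {
                "id": c.id,
                "variant": c.variant,
                "proband": c.proband,
                "family": c.family,
                "condition": c.condition,
                "phenotype_features": list(c.phenotype_features),
                "severity": c.severity,
                "onset": c.onset,
                "de_novo": c.de_novo,
                "zygosity": c.zygosity,
            }
            for c in bundle.cases
        ],
        "segregations": [
            {
                "id": s.id,
                "variant": s.variant,
                "family": s.family,
                "lod": s.lod,
                "affected_condition": s.affected_condition,
                "family_count": s.family_count,
            }
            for s in bundle.segregations
        ],
        "functionals": [
            {
                "id": f.id,
                "variant": f.variant,
                "assay": f.assay,
                "effect": f.effect,
                "mechanism_concordant": f.mechanism_concordant,
            }
            for f in bundle.functionals
        ],
        "populations": [
            {
                "id": p.id,
                "variant": p.variant,
                "cohort": p.cohort,
                "allele_count": p.allele_count,
                "allele_number": p.allele_number,
            }
            for p in bundle.populations
        ],
    }


def _tupled(d: dict, key: str):
    value = d.get(key, [])
    if not isinstance(value, list):
        raise BundleValidationError(f"field {key!r} must be a list")
    return value


def bundle_from_dict(data: dict) -> EvidenceBundle:
    if not isinstance(data, dict):
        raise BundleValidationError("bundle document must be a JSON object")
    unknown = set(data) - set(_COLLECTIONS)
    if unknown:
        raise BundleValidationError(f"unknown top-level keys: {sorted(unknown)}")

    def build(cls, items: list, collection: str, **renames):
        out = []
        for i, item in enumerate(items):
            if not isinstance(item, dict):
                raise BundleValidationError(
                    f"{collection}[{i}] must be an object"
                )
            kwargs = dict(item)
            try:
                if "aliases" in kwargs:
                    kwargs["aliases"] = tuple(kwargs["aliases"])
                if "preliminary_links" in kwargs:
                    kwargs["preliminary_links"] = tuple(
                        (str(c), str(k)) for c, k in kwargs["preliminary_links"]
                    )
                if "inheritance" in kwargs:
                    kwargs["inheritance"] = frozenset(kwargs["inheritance"])
                if "features" in kwargs:
                    kwargs["features"] = tuple(kwargs["features"])
                if "phenotype_features" in kwargs:
                    kwargs["phenotype_features"] = tuple(kwargs["phenotype_features"])
                out.append(cls(**kwargs))
            except TypeError as exc:
                rec_id = item.get("id", item.get("symbol", f"#{i}"))
                raise BundleValidationError(
                    f"{collection} record {rec_id!r}: {exc}"
                ) from None
        return tuple(out)

    return EvidenceBundle(
        genes=build(GeneRecord, _tupled(data, "genes"), "genes"),
        conditions=build(ConditionRecord, _tupled(data, "conditions"), "conditions"),
        variants=build(VariantRecord, _tupled(data, "variants"), "variants"),
        cases=build(CaseObservation, _tupled(data, "cases"), "cases"),
        segregations=build(SegregationDatum, _tupled(data, "segregations"), "segregations"),
        functionals=build(FunctionalDatum, _tupled(data, "functionals"), "functionals"),
        populations=build(PopulationDatum, _tupled(data, "populations"), "populations"),
    )


def load_bundle(path: str | Path) -> EvidenceBundle:
    """Load and validate an evidence bundle from a JSON file.

    Raises
    ------
    BundleValidationError
        If the document does not parse into the bundle dialect.
    BundleIntegrityError
        If a cross-reference dangles or an id is duplicated.
    """
    path = Path(path)
    with path.open("r", encoding="utf-8") as fh:
        try:
            data = json.load(fh)
        except json.JSONDecodeError as exc:
            raise BundleValidationError(f"{path}: not valid JSON: {exc}") from None
    return bundle_from_dict(data)


def write_bundle(bundle: EvidenceBundle, path: str | Path) -> None:
    """Write *bundle* as UTF-8 JSON so that :func:`load_bundle` round-trips."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        json.dump(bundle_to_dict(bundle), fh, indent=1, ensure_ascii=False)
        fh.write("\n")
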