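"""Machine-readable exports of assessment and panel results."""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import pandas as pd

from .engine import AssessmentResult
from .evidence import EvidenceBundle
from .panels import PanelSpec

__all__ = [
    "assertion_matrix",
    "write_assertion_matrix",
    "assessment_report",
    "write_assessment_report",
    "panel_to_dict",
    "write_panel",
    "load_assertions_report",
]


def assertion_matrix(result: AssessmentResult,
                     bundle: EvidenceBundle) -> pd.DataFrame:
    """Genes x conditions strength matrix (empty cell = no relationship).

    Generic "<GENE>-related" entities are omitted; the matrix mirrors the
    shape of a published gene-condition strength table.
    """
    genes = sorted({a.gene for a in result.assertions})
    conditions = sorted(
        c.id for c in bundle.conditions if not c.is_generic
    )
    df = pd.DataFrame("", index=genes, columns=conditions, dtype=object)
    for a in result.assertions:
        if a.is_generic or a.strength == "none":
            continue
        df.loc[a.gene, a.condition] = a.strength
    df.index.name = "gene"
    return df


def write_assertion_matrix(result: AssessmentResult, bundle: EvidenceBundle,
                           path: str | Path) -> None:
    assertion_matrix(result, bundle).to_csv(path, sep="\t")


def assessment_report(result: AssessmentResult) -> dict:
    """Full JSON-ready report: statuses, assertions, classifications."""
    return {
        "statuses": {
            g: {"status": s.status,
                "proving_variants": list(s.proving_variants)}
            for g, s in sorted(result.statuses.items())
        },
        "assertions": [
            {
                "gene": a.gene,
                "condition": a.condition,
                "strength": a.strength,
                "unrelated_proband_count": a.unrelated_proband_count,
                "pathogenic_variants": list(a.pathogenic_variants),
                "expansion_flag": a.expansion_flag,
                "is_generic": a.is_generic,
            }
            for a in result.assertions
        ],
        "classifications": {
            vid: {
                "verdict": c.verdict,
                "criteria": [
                    {k: (list(v) if isinstance(v, tuple) else v)
                     for k, v in asdict(cr).items()}
                    for cr in c.criteria
                ],
            }
            for vid, c in sorted(result.classifications.items())
        },
        "n_iterations": result.n_iterations,
    }


def write_assessment_report(result: AssessmentResult, path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        json.dump(assessment_report(result), fh, indent=1, ensure_ascii=False)
        fh.write("\n")


def load_assertions_report(path: str | Path) -> list:
    """Re-hydrate GeneConditionAssertion records from an assessment report."""
    from .engine import GeneConditionAssertion

    with Path(path).open("r", encoding="utf-8") as fh:
        data = json.load(fh)
    return [
        GeneConditionAssertion(
            gene=a["gene"],
            condition=a["condition"],
            strength=a["strength"],
            unrelated_proband_count=a.get("unrelated_proband_count", 0),
            pathogenic_variants=tuple(a.get("pathogenic_variants", ())),
            expansion_flag=a.get("expansion_flag", "not_applicable"),
            is_generic=a.get("is_generic", False),
        )
        for a in data["assertions"]
    ]


def panel_to_dict(panel: PanelSpec) -> dict:
    return {
        "target_condition": panel.target_condition,
        "entries": [
            {"gene": e.gene, "class": e.gene_class} for e in panel.entries
        ],
        "validity": panel.validity,
        "missing_required": list(panel.missing_required),
    }


def write_panel(panel: PanelSpec, path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        json.dump(panel_to_dict(panel), fh, indent=1, ensure_ascii=False)
        fh.write("\n")
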