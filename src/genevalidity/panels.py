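"""Diagnostic panel composition and validation over overlapping phenotypes.

A panel targeted at one presenting condition includes three classes of
genes:

1. ``proven_for_condition`` — conclusively proven to cause the target
   (a strong gene-condition assertion);
2. ``suspected_for_condition`` — emerging or suggested for the target;
3. ``proven_for_differential`` — conclusively proven to cause a condition
   in the target's clinical differential (a condition whose true
   presentation can mimic, progress to, or syndromically include the
   target).

The differential comes from a curated overlap map (presenting feature ->
set of true underlying conditions) shipped as an editable data file. A
panel is clinically valid only if it contains every gene that accounts
for a substantial share of the target's known genetic risk, per a curated
yield table.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from importlib import resources
from pathlib import Path

import pandas as pd

from .config import DEFAULT_CONFIG, RunConfig
from .engine import GeneConditionAssertion

__all__ = [
    "GENE_CLASSES",
    "GUIDANCE",
    "OverlapMap",
    "YieldRow",
    "PanelEntry",
    "PanelSpec",
    "load_overlap_map",
    "load_yield_table",
    "default_overlap_map",
    "default_yield_table",
    "differential",
    "classify_panel_gene",
    "design_panel",
    "validate_panel",
    "interpret_result",
]

GENE_CLASSES = (
    "proven_for_condition",
    "suspected_for_condition",
    "proven_for_differential",
)
_CLASS_RANK = {c: i for i, c in enumerate(GENE_CLASSES)}

GUIDANCE = (
    "diagnostic_actionable",
    "segregation_studies_suggested",
    "expansion_or_incidental",
    "clinical_rereview_suggested",
    "research_hold",
    "no_action",
)


class OverlapMap(dict):
    """Presenting condition token -> set of true underlying condition tokens."""

    def __init__(self, mapping: dict[str, set[str]]):
        super().__init__({k: frozenset(v) for k, v in mapping.items()})


@dataclass(frozen=True)
class YieldRow:
    gene: str
    condition: str
    substantial: bool
    yield_fraction: float | None = None

    def __post_init__(self) -> None:
        if self.yield_fraction is not None and not (0 <= self.yield_fraction <= 1):
            raise ValueError(
                f"{self.gene}/{self.condition}: yield fraction must be in [0, 1]"
            )


@dataclass(frozen=True)
class PanelEntry:
    gene: str
    gene_class: str

    def __post_init__(self) -> None:
        if self.gene_class not in GENE_CLASSES:
            raise ValueError(f"unknown panel gene class {self.gene_class!r}")


@dataclass(frozen=True)
class PanelSpec:
    target_condition: str
    entries: tuple[PanelEntry, ...] = ()
    validity: str | None = None  # valid | invalid | None (unvalidated)
    missing_required: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.validity not in (None, "valid", "invalid"):
            raise ValueError(f"unknown validity {self.validity!r}")
        if self.validity is not None and (
            (self.validity == "invalid") != bool(self.missing_required)
        ):
            raise ValueError("invalid iff missing_required non-empty")

    @property
    def genes(self) -> tuple[str, ...]:
        return tuple(e.gene for e in self.entries)


def load_overlap_map(path: str | Path) -> OverlapMap:
    with Path(path).open("r", encoding="utf-8") as fh:
        data = json.load(fh)
    if not isinstance(data, dict):
        raise ValueError(f"{path}: overlap map must be a JSON object")
    return OverlapMap({k: set(v) for k, v in data.items()})


def load_yield_table(path: str | Path) -> list[YieldRow]:
    df = pd.read_csv(path, sep="\t")
    required = {"gene", "condition", "substantial"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: yield table missing columns {sorted(missing)}")
    rows = []
    for rec in df.to_dict("records"):
        frac = rec.get("yield_fraction")
        frac = None if frac is None or pd.isna(frac) else float(frac)
        rows.append(YieldRow(
            gene=str(rec["gene"]),
            condition=str(rec["condition"]),
            substantial=bool(rec["substantial"]),
            yield_fraction=frac,
        ))
    return rows


def _data_path(name: str):
    return resources.files("genevalidity").joinpath("data", name)


def default_overlap_map() -> OverlapMap:
    """Curated cardiac presentation -> underlying-condition overlap map."""
    with resources.as_file(_data_path("overlap_cardiac.json")) as p:
        return load_overlap_map(p)


def default_yield_table() -> list[YieldRow]:
    """Curated cardiac gene diagnostic-yield table."""
    with resources.as_file(_data_path("yield_cardiac.tsv")) as p:
        return load_yield_table(p)


def differential(condition: str, overlap_map: OverlapMap) -> frozenset[str]:
    """Target condition plus every condition whose true presentation can
    mimic or progress to it."""
    if condition not in overlap_map:
        raise KeyError(f"condition {condition!r} not in overlap map")
    return frozenset(overlap_map[condition]) | {condition}


def classify_panel_gene(
    gene: str,
    target_condition: str,
    assertions: list[GeneConditionAssertion],
    overlap_map: OverlapMap,
) -> str | None:
    """Class of *gene* on a panel for *target_condition*, or None (excluded).

    Precedence: proven_for_condition > suspected_for_condition >
    proven_for_differential, so a gene strong for both the target and a
    differential condition is reported once, in its strongest role.
    Suggested links to a differential condition never qualify: class 3
    requires the differential relationship to be conclusively proven.
    """
    mine = {a.condition: a.strength for a in assertions
            if a.gene == gene and not a.is_generic}
    if mine.get(target_condition) == "strong":
        return "proven_for_condition"
    if mine.get(target_condition) in ("emerging", "suggested"):
        return "suspected_for_condition"
    for cond in differential(target_condition, overlap_map) - {target_condition}:
        if mine.get(cond) == "strong":
            return "proven_for_differential"
    return None


def design_panel(
    target_condition: str,
    assertions: list[GeneConditionAssertion],
    overlap_map: OverlapMap,
) -> PanelSpec:
    """Assemble the (unvalidated) panel for *target_condition*.

    Deterministic ordering: by class, then gene symbol; a gene appears at
    most once.
    """
    if target_condition not in overlap_map:
        raise KeyError(f"condition {target_condition!r} not in overlap map")
    genes = sorted({a.gene for a in assertions})
    entries = []
    for g in genes:
        cls = classify_panel_gene(g, target_condition, assertions, overlap_map)
        if cls is not None:
            entries.append(PanelEntry(gene=g, gene_class=cls))
    entries.sort(key=lambda e: (_CLASS_RANK[e.gene_class], e.gene))
    return PanelSpec(target_condition=target_condition, entries=tuple(entries))


def validate_panel(
    panel: PanelSpec,
    yield_table: list[YieldRow],
    config: RunConfig = DEFAULT_CONFIG,
) -> PanelSpec:
    """Fill in validity: invalid iff a substantial-yield gene is missing.

    A gene is substantial for the target when its curated flag is set or
    its yield fraction reaches the configured threshold.
    """
    relevant = [r for r in yield_table if r.condition == panel.target_condition]
    if not relevant:
        raise ValueError(
            f"yield table has no rows for condition {panel.target_condition!r}"
        )
    required = sorted({
        r.gene for r in relevant
        if r.substantial or (
            r.yield_fraction is not None
            and r.yield_fraction >= config.yield_fraction_threshold
        )
    })
    on_panel = set(panel.genes)
    missing = tuple(g for g in required if g not in on_panel)
    return replace(
        panel,
        validity="invalid" if missing else "valid",
        missing_required=missing,
    )


def interpret_result(gene_class: str, verdict: str) -> str:
    """Clinical-utility guidance for a variant finding on a panel gene.

    Findings in proven genes are actionable (pathogenic) or worth family
    segregation studies (VUS); findings in differential-condition genes
    signal phenotype expansion or an incidental second condition
    (pathogenic) or clinical re-review (VUS); findings in suspected-only
    genes are held for research and never guide care. Benign-side verdicts
    require no action anywhere.
    """
    if gene_class not in GENE_CLASSES:
        raise ValueError(f"unknown panel gene class {gene_class!r}")
    if verdict not in ("pathogenic", "likely_pathogenic", "VUS",
                      "likely_benign", "benign"):
        raise ValueError(f"unknown verdict {verdict!r}")
    if verdict in ("benign", "likely_benign"):
        return "no_action"
    if gene_class == "suspected_for_condition":
        return "research_hold"
    if gene_class == "proven_for_condition":
        if verdict in ("pathogenic", "likely_pathogenic"):
            return "diagnostic_actionable"
        return "segregation_studies_suggested"
    # proven_for_differential
    if verdict in ("pathogenic", "likely_pathogenic"):
        return "expansion_or_incidental"
    return "clinical_rereview_suggested"
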