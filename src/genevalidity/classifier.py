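"""Variant pathogenicity classification from structured evidence.

The classifier works in two stages:

1. :func:`assign_criteria` scans a variant's evidence records and emits
   weighted evidence criteria (pathogenic side: very strong / strong /
   moderate / supporting; benign side: stand-alone / strong / supporting).
2. :func:`combine_criteria` combines the criteria into a five-level
   verdict (pathogenic, likely_pathogenic, VUS, likely_benign, benign)
   using a fixed combining table.

Evidence modulation
-------------------
Two cautions couple criterion strength to gene-level knowledge. Until the
relationship between the gene and the observed condition is *strong*:

* case-count evidence (multiple unrelated, similarly affected probands)
  is down-weighted to supporting, because the relevance of the presenting
  phenotype is unestablished;
* molecular-consequence evidence (truncating / loss-of-function variant
  classes) is down-weighted to supporting, because the disease mechanism
  is unestablished.

Functional assays carry strong weight only when the assay demonstrates the
disease-relevant mechanism (``mechanism_concordant``); otherwise they are
supporting. Segregation is direct statistical evidence and is never
down-weighted, and a confirmed de novo observation in a severe, early-onset
phenotype retains strong weight regardless of link status — these are what
allow a gene to be proven in the first place. Benign-side frequency
evidence applies regardless of link status.

Every down-weighting is recorded on the criterion (``modulated_from``), so
classifications are fully auditable.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

from .config import DEFAULT_CONFIG, RunConfig
from .evidence import EvidenceBundle

__all__ = [
    "PATH_TIERS",
    "BENIGN_TIERS",
    "VERDICTS",
    "CriterionAssignment",
    "VariantClassification",
    "segregation_tier",
    "assign_criteria",
    "combine_criteria",
    "combine_criteria_table_scan",
    "classify_variant",
]

# pathogenic-side tiers, weakest to strongest
PATH_TIERS = ("path_supporting", "path_moderate", "path_strong", "path_very_strong")
BENIGN_TIERS = ("benign_supporting", "benign_strong", "benign_standalone")
CRITERION_CODES = PATH_TIERS + BENIGN_TIERS

# verdicts ordered from most benign to most pathogenic
VERDICTS = ("benign", "likely_benign", "VUS", "likely_pathogenic", "pathogenic")

_PATH_RANK = {code: i for i, code in enumerate(PATH_TIERS)}

# loss-of-function variant classes eligible for the molecular-consequence
# criterion when the disease mechanism is established
_LOF_CONSEQUENCES = frozenset({"nonsense", "frameshift", "splice", "exonic_deletion"})


@dataclass(frozen=True)
class CriterionAssignment:
    """One triggered evidence criterion.

    ``modulated_from`` records the original (stronger) tier when the
    criterion was down-weighted by a modulation caution.
    """

    code: str
    kind: str  # evidence family: segregation, functional, case_count, ...
    source: tuple[str, ...] = ()
    modulated_from: str | None = None
    note: str = ""

    def __post_init__(self) -> None:
        if self.code not in CRITERION_CODES:
            raise ValueError(f"unknown criterion code {self.code!r}")
        if self.modulated_from is not None:
            if self.modulated_from not in _PATH_RANK or self.code not in _PATH_RANK:
                raise ValueError("modulation applies to pathogenic-side tiers only")
            if _PATH_RANK[self.modulated_from] <= _PATH_RANK[self.code]:
                raise ValueError(
                    f"modulated_from {self.modulated_from!r} must be stronger "
                    f"than code {self.code!r}"
                )


@dataclass(frozen=True)
class VariantClassification:
    variant: str
    verdict: str
    criteria: tuple[CriterionAssignment, ...] = ()

    def __post_init__(self) -> None:
        if self.verdict not in VERDICTS:
            raise ValueError(f"unknown verdict {self.verdict!r}")


def segregation_tier(lod: float, config: RunConfig = DEFAULT_CONFIG) -> str:
    """Map a (possibly multi-family combined) LOD score to an evidence tier.

    Monotone non-decreasing in ``lod``; LOD >= 3.0 — the classical linkage
    significance bound — is strong by default.
    """
    lod = float(lod)
    if lod != lod or abs(lod) == float("inf"):
        raise ValueError("LOD score must be finite")
    if lod >= config.lod_strong:
        return "strong"
    if lod >= config.lod_moderate:
        return "moderate"
    if lod >= config.lod_supporting:
        return "supporting"
    return "none"


_SEG_TIER_CODE = {
    "strong": "path_strong",
    "moderate": "path_moderate",
    "supporting": "path_supporting",
}


def _capped(code: str, cap: str, kind: str, source: tuple[str, ...],
            note: str) -> CriterionAssignment:
    """Return the criterion, down-weighted to *cap* if *code* is stronger."""
    if _PATH_RANK[code] > _PATH_RANK[cap]:
        return CriterionAssignment(code=cap, kind=kind, source=source,
                                   modulated_from=code, note=note)
    return CriterionAssignment(code=code, kind=kind, source=source)


def _phenotype_match(case, condition, config: RunConfig) -> bool:
    """Does the case manifest the condition (id match or feature overlap)?"""
    if case.condition == condition.id:
        return True
    if not condition.features:
        return False
    hit = sum(1 for tok in condition.features if tok in case.phenotype_features)
    return hit / len(condition.features) >= config.phenotype_match_fraction


def assign_criteria(
    bundle: EvidenceBundle,
    variant_id: str,
    gene_status: dict[str, str] | None = None,
    link_strength: dict[tuple[str, str], str] | None = None,
    config: RunConfig = DEFAULT_CONFIG,
) -> list[CriterionAssignment]:
    """Scan a variant's evidence and emit all triggered criteria.

    ``gene_status`` maps gene symbol to ``proven``/``uncertain`` and
    ``link_strength`` maps (gene, condition) to a strength tier; both
    default to maximally conservative (uncertain, no strong links).
    """
    variant = bundle.variant(variant_id)  # raises on unknown id
    gene_status = gene_status or {}
    link_strength = link_strength or {}

    def link_is_strong(condition_id: str) -> bool:
        return link_strength.get((variant.gene, condition_id)) == "strong"

    criteria: list[CriterionAssignment] = []
    cases = bundle.cases_of(variant_id)

    # --- segregation: sum of combined LODs across independent family sets
    segs = bundle.segregations_of(variant_id)
    if segs:
        total_lod = sum(s.lod for s in segs)
        tier = segregation_tier(total_lod, config)
        if tier != "none":
            criteria.append(CriterionAssignment(
                code=_SEG_TIER_CODE[tier],
                kind="segregation",
                source=tuple(s.id for s in segs),
                note=f"combined LOD {total_lod:g} across "
                     f"{sum(s.family_count for s in segs)} families",
            ))

    # --- functional assays (animal models folded in as an assay type)
    funcs = bundle.functionals_of(variant_id)
    effectful = [f for f in funcs if f.effect != "no_effect"]
    if effectful:
        concordant = [f for f in effectful if f.mechanism_concordant]
        if concordant:
            criteria.append(CriterionAssignment(
                code="path_strong", kind="functional",
                source=tuple(f.id for f in effectful),
                note="assay demonstrates the disease-relevant mechanism",
            ))
        else:
            criteria.append(CriterionAssignment(
                code="path_supporting", kind="functional",
                source=tuple(f.id for f in effectful),
                modulated_from="path_strong",
                note="effect shown but mechanism concordance unestablished",
            ))
    elif funcs:  # only no-effect assays
        criteria.append(CriterionAssignment(
            code="benign_supporting", kind="functional",
            source=tuple(f.id for f in funcs),
            note="assays show no functional effect",
        ))

    # --- population frequency
    pops = bundle.populations_of(variant_id)
    frequent = [
        p for p in pops
        if p.frequency > config.benign_allele_frequency
        and p.allele_count >= config.benign_min_allele_count
    ]
    if frequent:
        criteria.append(CriterionAssignment(
            code="benign_strong", kind="frequency",
            source=tuple(p.id for p in frequent),
            note="allele frequency above the benign threshold for the "
                 "condition class",
        ))
    elif pops:
        total_an = sum(p.allele_number for p in pops)
        total_ac = sum(p.allele_count for p in pops)
        if total_ac == 0 and total_an >= config.absence_min_allele_number:
            criteria.append(CriterionAssignment(
                code="path_moderate", kind="absence",
                source=tuple(p.id for p in pops),
                note=f"absent from {total_an} control alleles",
            ))

    # --- case count: unrelated probands manifesting one specific condition
    by_condition: dict[str, set[str]] = {}
    for c in cases:
        by_condition.setdefault(c.condition, set()).add(c.family)
    best: CriterionAssignment | None = None
    for cond_id in sorted(by_condition):
        families = by_condition[cond_id]
        if len(families) < config.case_count_min_probands:
            continue
        src = tuple(c.id for c in cases if c.condition == cond_id)
        note = (f"{len(families)} unrelated probands with {cond_id}")
        if link_is_strong(cond_id):
            cand = CriterionAssignment(code="path_moderate", kind="case_count",
                                       source=src, note=note)
        else:
            cand = _capped("path_moderate", "path_supporting", "case_count",
                           src, note + "; gene-condition link unestablished")
        if best is None or _PATH_RANK[cand.code] > _PATH_RANK[best.code]:
            best = cand
    if best is not None:
        criteria.append(best)

    # --- de novo observations
    denovo_best: CriterionAssignment | None = None
    for c in cases:
        if c.de_novo == "none":
            continue
        if (c.de_novo == "confirmed_parentage" and c.severity == "severe"
                and c.onset in ("infantile", "childhood")):
            # severe early-onset confirmed de novo keeps strong weight
            # regardless of link status
            cand = CriterionAssignment(
                code="path_strong", kind="de_novo", source=(c.id,),
                note="confirmed de novo, severe early-onset phenotype",
            )
        elif c.de_novo == "confirmed_parentage":
            if link_is_strong(c.condition):
                cand = CriterionAssignment(
                    code="path_moderate", kind="de_novo", source=(c.id,),
                    note="confirmed de novo",
                )
            else:
                cand = _capped("path_moderate", "path_supporting", "de_novo",
                               (c.id,),
                               "confirmed de novo; gene-condition link "
                               "unestablished")
        else:  # assumed
            cand = CriterionAssignment(
                code="path_supporting", kind="de_novo", source=(c.id,),
                note="assumed de novo (parentage not confirmed)",
            )
        if denovo_best is None or _PATH_RANK[cand.code] > _PATH_RANK[denovo_best.code]:
            denovo_best = cand
    if denovo_best is not None:
        criteria.append(denovo_best)

    # --- molecular consequence (loss-of-function variant classes)
    if variant.consequence in _LOF_CONSEQUENCES:
        established = any(link_is_strong(c.condition) for c in cases)
        if established:
            criteria.append(CriterionAssignment(
                code="path_very_strong", kind="consequence", source=(variant.id,),
                note=f"{variant.consequence} in a gene with established "
                     "loss-of-function disease link",
            ))
        else:
            criteria.append(_capped(
                "path_very_strong", "path_supporting", "consequence",
                (variant.id,),
                f"{variant.consequence}; disease mechanism unestablished"))
    elif variant.consequence == "synonymous":
        criteria.append(CriterionAssignment(
            code="benign_supporting", kind="consequence", source=(variant.id,),
            note="synonymous change with no predicted impact",
        ))

    # --- pre-tagged computational support
    if variant.computational_support:
        criteria.append(CriterionAssignment(
            code="path_supporting", kind="computational", source=(variant.id,),
            note="in-silico predictors support a deleterious effect",
        ))

    return criteria


def _counts(criteria) -> dict[str, int]:
    counts = dict.fromkeys(CRITERION_CODES, 0)
    for c in criteria:
        code = c.code if isinstance(c, CriterionAssignment) else c
        if code not in counts:
            raise ValueError(f"malformed criterion code {code!r}")
        counts[code] += 1
    return counts


def combine_criteria(criteria) -> str:
    """Combine evidence criteria into a five-level verdict.

    *criteria* may be :class:`CriterionAssignment` objects or bare codes.
    The combining table is fixed; conflicting strong evidence on both
    sides yields VUS, as does any multiset matching no row.
    """
    n = _counts(criteria)
    vs, s, m, p = (n["path_very_strong"], n["path_strong"],
                   n["path_moderate"], n["path_supporting"])
    ba, bs, bp = n["benign_standalone"], n["benign_strong"], n["benign_supporting"]

    pathogenic = (
        (vs >= 1 and s >= 1)
        or (vs >= 1 and m >= 2)
        or (vs >= 1 and m >= 1 and p >= 1)
        or (vs >= 1 and p >= 2)
        or s >= 2
        or (s >= 1 and m >= 3)
        or (s >= 1 and m >= 2 and p >= 2)
        or (s >= 1 and m >= 1 and p >= 4)
    )
    likely_pathogenic = (
        (vs >= 1 and m >= 1)
        or (s >= 1 and m >= 1)
        or (s >= 1 and p >= 2)
        or m >= 3
        or (m >= 2 and p >= 2)
        or (m >= 1 and p >= 4)
    )
    benign = ba >= 1 or bs >= 2
    likely_benign = (bs >= 1 and bp >= 1) or bp >= 2

    path_verdict = ("pathogenic" if pathogenic
                    else "likely_pathogenic" if likely_pathogenic else None)
    benign_verdict = ("benign" if benign
                      else "likely_benign" if likely_benign else None)

    # Conflict rule: a side is active once it reaches a verdict or holds
    # strong evidence; two active sides disagree, and disagreement is VUS.
    # (The symmetric form keeps the combiner monotone in added evidence.)
    path_active = path_verdict is not None or vs + s >= 1
    benign_active = benign_verdict is not None or ba + bs >= 1
    if path_active and benign_active:
        return "VUS"
    return path_verdict or benign_verdict or "VUS"


# Literal row-by-row form of the combining table, used as an independent
# cross-check of combine_criteria. Each row: (requirements, verdict); a
# requirement maps a code to its minimum count.
_TABLE_ROWS: tuple[tuple[dict[str, int], str], ...] = (
    ({"path_very_strong": 1, "path_strong": 1}, "pathogenic"),
    ({"path_very_strong": 1, "path_moderate": 2}, "pathogenic"),
    ({"path_very_strong": 1, "path_moderate": 1, "path_supporting": 1}, "pathogenic"),
    ({"path_very_strong": 1, "path_supporting": 2}, "pathogenic"),
    ({"path_strong": 2}, "pathogenic"),
    ({"path_strong": 1, "path_moderate": 3}, "pathogenic"),
    ({"path_strong": 1, "path_moderate": 2, "path_supporting": 2}, "pathogenic"),
    ({"path_strong": 1, "path_moderate": 1, "path_supporting": 4}, "pathogenic"),
    ({"path_very_strong": 1, "path_moderate": 1}, "likely_pathogenic"),
    ({"path_strong": 1, "path_moderate": 1}, "likely_pathogenic"),
    ({"path_strong": 1, "path_supporting": 2}, "likely_pathogenic"),
    ({"path_moderate": 3}, "likely_pathogenic"),
    ({"path_moderate": 2, "path_supporting": 2}, "likely_pathogenic"),
    ({"path_moderate": 1, "path_supporting": 4}, "likely_pathogenic"),
    ({"benign_standalone": 1}, "benign"),
    ({"benign_strong": 2}, "benign"),
    ({"benign_strong": 1, "benign_supporting": 1}, "likely_benign"),
    ({"benign_supporting": 2}, "likely_benign"),
)

_VERDICT_PRIORITY = ("pathogenic", "likely_pathogenic", "benign", "likely_benign")


def combine_criteria_table_scan(criteria) -> str:
    """Reference combiner: literally scan every row of the combining table."""
    n = _counts(criteria)
    path_verdict = None
    benign_verdict = None
    for wanted in _VERDICT_PRIORITY:
        for requirements, verdict in _TABLE_ROWS:
            if verdict != wanted:
                continue
            if all(n[code] >= k for code, k in requirements.items()):
                if wanted in ("pathogenic", "likely_pathogenic"):
                    path_verdict = path_verdict or wanted
                else:
                    benign_verdict = benign_verdict or wanted
                break
    path_active = (path_verdict is not None
                   or n["path_very_strong"] + n["path_strong"] >= 1)
    benign_active = (benign_verdict is not None
                     or n["benign_standalone"] + n["benign_strong"] >= 1)
    if path_active and benign_active:
        return "VUS"
    return path_verdict or benign_verdict or "VUS"


def classify_variant(
    bundle: EvidenceBundle,
    variant_id: str,
    gene_status: dict[str, str] | None = None,
    link_strength: dict[tuple[str, str], str] | None = None,
    config: RunConfig = DEFAULT_CONFIG,
) -> VariantClassification:
    """Classify one variant; the verdict carries full criterion provenance."""
    criteria = tuple(assign_criteria(bundle, variant_id, gene_status,
                                     link_strength, config))
    return VariantClassification(
        variant=variant_id,
        verdict=combine_criteria(criteria),
        criteria=criteria,
    )
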