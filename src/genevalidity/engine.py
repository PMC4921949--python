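"""Gene-level clinical validity and condition-strength assertions.

The logical chain: a gene is *proven* to cause human disease exactly when
at least one clinically observed variant in it classifies as pathogenic.
A specific gene-condition relationship is *strong* when pathogenic
variants have been observed in at least three unrelated probands
manifesting the condition, *emerging* when one or two such probands exist
in an already-proven gene, and *suggested* when only preliminary evidence
(a VUS-only case series, linkage, functional or animal work) links the
pair. A gene with no strong relationship anywhere is a Gene of Uncertain
Significance (GUS). Whenever a gene is proven, the gene-anchored generic
entity "<GENE>-related conditions" is asserted strong, even if no specific
condition has reached three probands yet.

Fixed point
-----------
Variant classification is modulated by gene-condition link strength, and
link strength is derived from variant classifications — a circularity.
:func:`fixed_point_assess` resolves it by starting maximally conservative
(every gene uncertain, every link unestablished) and iterating
classify -> assess -> re-link until nothing changes. Strengthening a link
can only raise criterion tiers, raising tiers can only raise verdicts, and
raising verdicts can only raise statuses and counts, so the update is
monotone on a finite lattice and the iteration converges; the result is
independent of evaluation order.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

from .classifier import VariantClassification, classify_variant
from .config import DEFAULT_CONFIG, RunConfig
from .evidence import (
    BundleIntegrityError,
    ConditionRecord,
    EvidenceBundle,
    generic_condition_id,
)

__all__ = [
    "GeneStatus",
    "GeneConditionAssertion",
    "AssessmentResult",
    "count_unrelated_probands",
    "assess_gene",
    "assert_gene_condition",
    "phenotype_expansion_flag",
    "fixed_point_assess",
]

STRENGTHS = ("none", "suggested", "emerging", "strong")
_STRENGTH_RANK = {s: i for i, s in enumerate(STRENGTHS)}

EXPANSION_FLAGS = ("not_applicable", "complex_phenotype", "distinct_conditions")


@dataclass(frozen=True)
class GeneStatus:
    gene: str
    status: str  # proven | uncertain
    proving_variants: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.status not in ("proven", "uncertain"):
            raise ValueError(f"unknown gene status {self.status!r}")
        if (self.status == "proven") != bool(self.proving_variants):
            raise ValueError("status is proven iff proving_variants is non-empty")


@dataclass(frozen=True)
class GeneConditionAssertion:
    gene: str
    condition: str
    strength: str
    unrelated_proband_count: int = 0
    pathogenic_variants: tuple[str, ...] = ()
    expansion_flag: str = "not_applicable"
    is_generic: bool = False

    def __post_init__(self) -> None:
        if self.strength not in STRENGTHS:
            raise ValueError(f"unknown strength {self.strength!r}")
        if self.expansion_flag not in EXPANSION_FLAGS:
            raise ValueError(f"unknown expansion flag {self.expansion_flag!r}")
        if not self.is_generic:
            # generic assertions are strong whenever the gene is proven and
            # may legitimately carry fewer than three probands
            if self.strength == "strong" and (
                self.unrelated_proband_count < 3 or not self.pathogenic_variants
            ):
                raise ValueError(
                    f"{self.gene}/{self.condition}: strong requires >=3 "
                    "unrelated probands and a pathogenic variant"
                )
        if self.strength == "emerging" and not (
            1 <= self.unrelated_proband_count <= 2
        ):
            raise ValueError(
                f"{self.gene}/{self.condition}: emerging requires 1-2 probands"
            )
        if self.strength == "suggested" and self.pathogenic_variants:
            raise ValueError(
                f"{self.gene}/{self.condition}: suggested requires no "
                "pathogenic variants"
            )


@dataclass(frozen=True)
class AssessmentResult:
    statuses: dict[str, GeneStatus]
    assertions: tuple[GeneConditionAssertion, ...]
    classifications: dict[str, VariantClassification]
    n_iterations: int

    def assertion(self, gene: str, condition: str) -> GeneConditionAssertion:
        for a in self.assertions:
            if a.gene == gene and a.condition == condition:
                return a
        raise KeyError((gene, condition))

    def strength(self, gene: str, condition: str) -> str:
        return self.assertion(gene, condition).strength


def _case_matches(case, condition: ConditionRecord, config: RunConfig) -> bool:
    if case.condition == condition.id:
        return True
    if not condition.features:
        return False
    hit = sum(1 for tok in condition.features if tok in case.phenotype_features)
    return hit / len(condition.features) >= config.phenotype_match_fraction


def _qualifying_cases(
    bundle: EvidenceBundle,
    classifications: dict[str, VariantClassification],
    gene: str,
    condition: ConditionRecord,
    config: RunConfig,
):
    """Cases of *gene* that count toward (gene, condition) proband tallies.

    A case qualifies when its variant classifies pathogenic and the case
    manifests the condition. For a purely recessive condition, a
    heterozygous observation does not qualify; a compound-het proband
    qualifies only if every allele observed in that proband for the
    condition classifies pathogenic.
    """
    gene_variants = {v.id for v in bundle.variants_of(gene)}
    recessive = condition.inheritance == frozenset({"AR"})

    candidates = [
        c for c in bundle.cases
        if c.variant in gene_variants and _case_matches(c, condition, config)
        and classifications[c.variant].verdict == "pathogenic"
    ]
    if not recessive:
        return candidates

    out = []
    for c in candidates:
        if c.zygosity == "het":
            continue
        if c.zygosity == "compound_het":
            partner_alleles = [
                other for other in bundle.cases
                if other.proband == c.proband
                and other.condition == c.condition
                and other.variant in gene_variants
            ]
            if not all(
                classifications[o.variant].verdict == "pathogenic"
                for o in partner_alleles
            ):
                continue
        out.append(c)
    return out


def count_unrelated_probands(
    bundle: EvidenceBundle,
    classifications: dict[str, VariantClassification],
    gene: str,
    condition_id: str,
    config: RunConfig = DEFAULT_CONFIG,
) -> int:
    """Distinct family count of qualifying pathogenic-variant cases.

    A multi-generation pedigree shares one family id and therefore counts
    as a single unrelated proband.
    """
    bundle.gene(gene)  # raises on unknown gene
    condition = bundle.condition(condition_id)
    cases = _qualifying_cases(bundle, classifications, gene, condition, config)
    return len({c.family for c in cases})


def assess_gene(
    bundle: EvidenceBundle,
    classifications: dict[str, VariantClassification],
    gene: str,
) -> GeneStatus:
    """Gene is proven iff a clinically observed variant is pathogenic.

    "Clinically observed" requires at least one case observation; a
    variant with pathogenic-grade evidence but no affected carrier does
    not establish clinical validity.
    """
    bundle.gene(gene)
    proving = []
    for v in bundle.variants_of(gene):
        if not bundle.cases_of(v.id):
            continue
        cls = classifications.get(v.id)
        if cls is not None and cls.verdict == "pathogenic":
            proving.append(v.id)
    if proving:
        return GeneStatus(gene=gene, status="proven",
                          proving_variants=tuple(sorted(proving)))
    return GeneStatus(gene=gene, status="uncertain")


def assert_gene_condition(
    bundle: EvidenceBundle,
    classifications: dict[str, VariantClassification],
    status: GeneStatus,
    gene: str,
    condition_id: str,
    config: RunConfig = DEFAULT_CONFIG,
) -> GeneConditionAssertion:
    """Derive the strength assertion for one (gene, condition) pair."""
    gene_rec = bundle.gene(gene)
    condition = bundle.condition(condition_id)

    if condition.is_generic:
        if condition_id != generic_condition_id(gene):
            return GeneConditionAssertion(gene=gene, condition=condition_id,
                                          strength="none", is_generic=True)
        # generic assertion: strong whenever the gene is proven
        gene_variants = {v.id for v in bundle.variants_of(gene)}
        families = {
            c.family for c in bundle.cases
            if c.variant in gene_variants
            and classifications[c.variant].verdict == "pathogenic"
        }
        if status.status == "proven":
            return GeneConditionAssertion(
                gene=gene, condition=condition_id, strength="strong",
                unrelated_proband_count=len(families),
                pathogenic_variants=status.proving_variants, is_generic=True,
            )
        return GeneConditionAssertion(gene=gene, condition=condition_id,
                                      strength="none", is_generic=True)

    cases = _qualifying_cases(bundle, classifications, gene, condition, config)
    count = len({c.family for c in cases})
    path_variants = tuple(sorted({c.variant for c in cases}))
    if count > 0 and not path_variants:
        raise BundleIntegrityError(
            f"{gene}/{condition_id}: proband count {count} with no "
            "pathogenic variant"
        )

    if count >= config.strong_min_probands:
        return GeneConditionAssertion(
            gene=gene, condition=condition_id, strength="strong",
            unrelated_proband_count=count, pathogenic_variants=path_variants,
        )
    if 1 <= count <= 2 and status.status == "proven":
        return GeneConditionAssertion(
            gene=gene, condition=condition_id, strength="emerging",
            unrelated_proband_count=count, pathogenic_variants=path_variants,
        )
    if count == 0 and any(
        cond_id == condition_id for cond_id, _ in gene_rec.preliminary_links
    ):
        return GeneConditionAssertion(
            gene=gene, condition=condition_id, strength="suggested",
        )
    return GeneConditionAssertion(
        gene=gene, condition=condition_id, strength="none",
        unrelated_proband_count=count, pathogenic_variants=path_variants,
    )


def phenotype_expansion_flag(
    assertions: list[GeneConditionAssertion],
    bundle: EvidenceBundle,
    classifications: dict[str, VariantClassification],
    config: RunConfig = DEFAULT_CONFIG,
) -> dict[str, str]:
    """Judge whether secondary conditions of a gene expand its phenotype.

    Among a gene's non-generic assertions of at least emerging strength,
    the condition with the most probands is the primary; each other
    condition is flagged:

    * ``distinct_conditions`` — its qualifying proband set is disjoint
      from the primary's and the two conditions differ in inheritance
      mode (e.g. a recessive syndrome vs. the dominant carrier phenotype);
    * ``complex_phenotype`` — a proband manifests features of both
      conditions, or a pathogenic variant recurs in probands of each;
    * ``not_applicable`` otherwise.
    """
    qualifying = [
        a for a in assertions
        if not a.is_generic and _STRENGTH_RANK[a.strength] >= _STRENGTH_RANK["emerging"]
    ]
    flags = {a.condition: "not_applicable" for a in assertions if not a.is_generic}
    if len(qualifying) < 2:
        return flags

    gene = qualifying[0].gene
    primary = max(qualifying,
                  key=lambda a: (a.unrelated_proband_count, a.condition))
    primary_cond = bundle.condition(primary.condition)
    primary_cases = _qualifying_cases(bundle, classifications, gene,
                                      primary_cond, config)
    primary_probands = {c.proband for c in primary_cases}
    primary_variants = {c.variant for c in primary_cases}

    for a in qualifying:
        if a.condition == primary.condition:
            continue
        other_cond = bundle.condition(a.condition)
        other_cases = _qualifying_cases(bundle, classifications, gene,
                                        other_cond, config)
        other_probands = {c.proband for c in other_cases}
        other_variants = {c.variant for c in other_cases}

        disjoint = not (primary_probands & other_probands)
        inheritance_differs = primary_cond.inheritance != other_cond.inheritance
        if disjoint and inheritance_differs:
            flags[a.condition] = "distinct_conditions"
            continue

        shared_proband = bool(primary_probands & other_probands)
        shared_variant = bool(primary_variants & other_variants)
        both_features = any(
            _case_matches(c, primary_cond, config)
            and _case_matches(c, other_cond, config)
            for c in primary_cases + other_cases
        )
        if shared_proband or shared_variant or both_features:
            flags[a.condition] = "complex_phenotype"
    return flags


def fixed_point_assess(
    bundle: EvidenceBundle,
    config: RunConfig = DEFAULT_CONFIG,
) -> AssessmentResult:
    """Run classify/assess to convergence from a conservative start.

    All genes start uncertain and all links unestablished; each iteration
    reclassifies every variant under the current maps and recomputes
    statuses and assertions. The monotone update converges in at most
    ``len(genes) + 1`` sweeps on bundles where each released modulation
    cap traces back to a newly proven gene.
    """
    genes = sorted(g.symbol for g in bundle.genes)
    conditions = sorted(c.id for c in bundle.conditions)

    status_map: dict[str, str] = {g: "uncertain" for g in genes}
    link_map: dict[tuple[str, str], str] = {}

    statuses: dict[str, GeneStatus] = {
        g: GeneStatus(gene=g, status="uncertain") for g in genes
    }
    assertions: tuple[GeneConditionAssertion, ...] = ()
    classifications: dict[str, VariantClassification] = {}

    n_iterations = 0
    while True:
        n_iterations += 1
        classifications = {
            v.id: classify_variant(bundle, v.id, status_map, link_map, config)
            for v in bundle.variants
        }
        statuses = {g: assess_gene(bundle, classifications, g) for g in genes}

        new_assertions = []
        for g in genes:
            gene_generic = generic_condition_id(g)
            for cond_id in conditions:
                cond = bundle.condition(cond_id)
                if cond.is_generic and cond_id != gene_generic:
                    continue  # generic entities belong to one gene
                new_assertions.append(assert_gene_condition(
                    bundle, classifications, statuses[g], g, cond_id, config
                ))
        assertions = tuple(new_assertions)

        new_status_map = {g: statuses[g].status for g in genes}
        new_link_map = {
            (a.gene, a.condition): a.strength
            for a in assertions if not a.is_generic
        }
        if new_status_map == status_map and new_link_map == link_map:
            break
        status_map, link_map = new_status_map, new_link_map
        if n_iterations > len(genes) + len(conditions) + 2:  # safety valve
            raise RuntimeError("fixed-point assessment failed to converge")

    # post-convergence: phenotype-expansion judgment per gene
    flagged = []
    for g in genes:
        gene_assertions = [a for a in assertions if a.gene == g]
        flags = phenotype_expansion_flag(gene_assertions, bundle,
                                         classifications, config)
        for a in gene_assertions:
            if not a.is_generic and flags.get(a.condition, "not_applicable") != "not_applicable":
                a = replace(a, expansion_flag=flags[a.condition])
            flagged.append(a)

    return AssessmentResult(
        statuses=statuses,
        assertions=tuple(flagged),
        classifications=classifications,
        n_iterations=n_iterations,
    )
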