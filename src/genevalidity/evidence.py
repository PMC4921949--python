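"""Domain model for structured gene/variant evidence.

The unit of work is an :class:`EvidenceBundle`: everything known about a set
of genes — the conditions they are purported to cause, the clinically
observed variants, case observations in affected individuals, family
segregation data, functional assay results, and population allele counts.
Bundles are plain data with strict validation: every cross-reference must
resolve, identifiers must be unique, and enumerated fields are closed.

Identity conventions
--------------------
* Gene symbols are HGNC-style uppercase tokens and are the gene keys.
* Conditions are flat tokens, not an ontology. Each gene may have at most
  one *generic* condition ("<GENE>-related conditions", id
  ``"<GENE>-related"``), the gene-anchored entity used before a specific
  condition can be named.
* Unrelatedness is encoded purely by distinct family ids: two case
  observations with different ``family`` values are unrelated individuals.
* HGVS strings are opaque, syntax-checked tokens; no coordinate or
  transcript-level normalization is performed or needed.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, fields as dc_fields

__all__ = [
    "PRELIMINARY_KINDS",
    "INHERITANCE_MODES",
    "CONSEQUENCES",
    "SEVERITIES",
    "ONSETS",
    "DE_NOVO_STATES",
    "ZYGOSITIES",
    "ASSAYS",
    "EFFECTS",
    "BundleValidationError",
    "BundleIntegrityError",
    "GeneRecord",
    "ConditionRecord",
    "VariantRecord",
    "CaseObservation",
    "SegregationDatum",
    "FunctionalDatum",
    "PopulationDatum",
    "EvidenceBundle",
    "generic_condition_id",
]

PRELIMINARY_KINDS = frozenset(
    {"case_series_vus_only", "linkage_only", "functional_only", "animal_only"}
)
INHERITANCE_MODES = frozenset({"AD", "AR", "XL"})
CONSEQUENCES = frozenset(
    {"missense", "nonsense", "frameshift", "splice", "exonic_deletion",
     "synonymous", "other"}
)
SEVERITIES = frozenset({"mild", "classic", "severe"})
ONSETS = frozenset({"infantile", "childhood", "adult"})
DE_NOVO_STATES = frozenset({"none", "assumed", "confirmed_parentage"})
ZYGOSITIES = frozenset({"het", "hom", "compound_het"})
ASSAYS = frozenset({"biochemical", "cellular", "animal_model"})
EFFECTS = frozenset({"loss_of_function", "gain_of_function", "no_effect"})

_GENE_SYMBOL_RE = re.compile(r"^[A-Z][A-Z0-9-]*$")
_HGVS_RE = re.compile(r"^[cpgmn]\.\S+$")


class BundleValidationError(ValueError):
    """A record violates a field-level invariant (bad enum, empty id, ...)."""


class BundleIntegrityError(ValueError):
    """A cross-record invariant is violated (dangling reference, duplicate id)."""


def generic_condition_id(gene_symbol: str) -> str:
    """Condition id of the gene-anchored generic entity for *gene_symbol*."""
    return f"{gene_symbol}-related"


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise BundleValidationError(msg)


@dataclass(frozen=True)
class GeneRecord:
    """A gene under curation.

    ``preliminary_links`` lists (condition id, evidence kind) pairs recording
    pre-proof evidence — case series of VUS-only observations, linkage alone,
    functional or animal-model work alone — the basis for a *suggested*
    gene–condition relationship.
    """

    symbol: str
    aliases: tuple[str, ...] = ()
    preliminary_links: tuple[tuple[str, str], ...] = ()

    def __post_init__(self) -> None:
        _require(bool(self.symbol), "gene symbol must be non-empty")
        _require(
            _GENE_SYMBOL_RE.match(self.symbol) is not None,
            f"gene symbol {self.symbol!r} is not an uppercase HGNC-style token",
        )
        for cond_id, kind in self.preliminary_links:
            _require(
                kind in PRELIMINARY_KINDS,
                f"gene {self.symbol}: unknown preliminary evidence kind {kind!r}",
            )
            _require(bool(cond_id), f"gene {self.symbol}: empty condition id in link")


@dataclass(frozen=True)
class ConditionRecord:
    """A clinical condition token.

    ``features`` are flat phenotype tokens used for partial matching of case
    observations against the condition (no HPO reasoning). ``is_generic``
    marks the gene-anchored "<GENE>-related conditions" entity.
    """

    id: str
    name: str
    inheritance: frozenset[str] = frozenset()
    is_syndromic: bool = False
    is_generic: bool = False
    features: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        _require(bool(self.id), "condition id must be non-empty")
        object.__setattr__(self, "inheritance", frozenset(self.inheritance))
        unknown = self.inheritance - INHERITANCE_MODES
        _require(not unknown, f"condition {self.id}: unknown inheritance {sorted(unknown)}")


@dataclass(frozen=True)
class VariantRecord:
    """A clinically observed (or at least curated) sequence variant.

    ``computational_support`` is a pre-tagged flag meaning in-silico
    predictors support a deleterious effect; it is the only form in which
    computational evidence enters the framework.
    """

    id: str
    gene: str
    hgvs: str
    consequence: str
    computational_support: bool = False

    def __post_init__(self) -> None:
        _require(bool(self.id), "variant id must be non-empty")
        _require(bool(self.gene), f"variant {self.id}: gene must be non-empty")
        _require(
            _HGVS_RE.match(self.hgvs) is not None,
            f"variant {self.id}: HGVS string {self.hgvs!r} fails syntax check",
        )
        _require(
            self.consequence in CONSEQUENCES,
            f"variant {self.id}: unknown consequence {self.consequence!r}",
        )


@dataclass(frozen=True)
class CaseObservation:
    """One observation of a variant in one affected individual."""

    id: str
    variant: str
    proband: str
    family: str
    condition: str
    phenotype_features: tuple[str, ...] = ()
    severity: str = "classic"
    onset: str = "adult"
    de_novo: str = "none"
    zygosity: str = "het"

    def __post_init__(self) -> None:
        for name in ("id", "variant", "proband", "family", "condition"):
            _require(bool(getattr(self, name)), f"case {self.id!r}: empty {name}")
        _require(self.severity in SEVERITIES, f"case {self.id}: bad severity {self.severity!r}")
        _require(self.onset in ONSETS, f"case {self.id}: bad onset {self.onset!r}")
        _require(self.de_novo in DE_NOVO_STATES, f"case {self.id}: bad de_novo {self.de_novo!r}")
        _require(self.zygosity in ZYGOSITIES, f"case {self.id}: bad zygosity {self.zygosity!r}")


@dataclass(frozen=True)
class SegregationDatum:
    """Family segregation of a variant with a condition.

    ``lod`` is the log10 odds of co-segregation; it may be a combined
    multi-family value, in which case ``family_count`` > 1 and ``family``
    names the family group.
    """

    id: str
    variant: str
    family: str
    lod: float
    affected_condition: str
    family_count: int = 1

    def __post_init__(self) -> None:
        _require(bool(self.id), "segregation datum id must be non-empty")
        lod = float(self.lod)
        _require(lod == lod and abs(lod) != float("inf"),
                 f"segregation {self.id}: LOD must be finite")
        object.__setattr__(self, "lod", lod)
        _require(self.family_count >= 1, f"segregation {self.id}: family_count must be >= 1")


@dataclass(frozen=True)
class FunctionalDatum:
    """A functional assay result for a variant.

    ``mechanism_concordant`` is True when the assay demonstrates the
    disease-relevant molecular mechanism (not merely *an* effect).
    """

    id: str
    variant: str
    assay: str
    effect: str
    mechanism_concordant: bool = False

    def __post_init__(self) -> None:
        _require(bool(self.id), "functional datum id must be non-empty")
        _require(self.assay in ASSAYS, f"functional {self.id}: unknown assay {self.assay!r}")
        _require(self.effect in EFFECTS, f"functional {self.id}: unknown effect {self.effect!r}")


@dataclass(frozen=True)
class PopulationDatum:
    """Allele count of a variant in a (presumed healthy) population cohort."""

    id: str
    variant: str
    cohort: str
    allele_count: int
    allele_number: int

    def __post_init__(self) -> None:
        _require(bool(self.id), "population datum id must be non-empty")
        _require(self.allele_number > 0,
                 f"population {self.id}: allele_number must be positive")
        _require(0 <= self.allele_count <= self.allele_number,
                 f"population {self.id}: allele_count must be in [0, allele_number]")

    @property
    def frequency(self) -> float:
        return self.allele_count / self.allele_number


@dataclass(frozen=True)
class EvidenceBundle:
    """The full structured evidence store for a curation run."""

    genes: tuple[GeneRecord, ...] = ()
    conditions: tuple[ConditionRecord, ...] = ()
    variants: tuple[VariantRecord, ...] = ()
    cases: tuple[CaseObservation, ...] = ()
    segregations: tuple[SegregationDatum, ...] = ()
    functionals: tuple[FunctionalDatum, ...] = ()
    populations: tuple[PopulationDatum, ...] = ()

    def __post_init__(self) -> None:
        self.validate()

    # -- keyed views -------------------------------------------------------

    def gene(self, symbol: str) -> GeneRecord:
        try:
            return self._gene_index[symbol]
        except KeyError:
            raise BundleIntegrityError(f"unknown gene {symbol!r}") from None

    def condition(self, cond_id: str) -> ConditionRecord:
        try:
            return self._condition_index[cond_id]
        except KeyError:
            raise BundleIntegrityError(f"unknown condition {cond_id!r}") from None

    def variant(self, variant_id: str) -> VariantRecord:
        try:
            return self._variant_index[variant_id]
        except KeyError:
            raise BundleIntegrityError(f"unknown variant {variant_id!r}") from None

    @property
    def _gene_index(self) -> dict[str, GeneRecord]:
        return {g.symbol: g for g in self.genes}

    @property
    def _condition_index(self) -> dict[str, ConditionRecord]:
        return {c.id: c for c in self.conditions}

    @property
    def _variant_index(self) -> dict[str, VariantRecord]:
        return {v.id: v for v in self.variants}

    def variants_of(self, gene_symbol: str) -> list[VariantRecord]:
        return [v for v in self.variants if v.gene == gene_symbol]

    def cases_of(self, variant_id: str) -> list[CaseObservation]:
        return [c for c in self.cases if c.variant == variant_id]

    def segregations_of(self, variant_id: str) -> list[SegregationDatum]:
        return [s for s in self.segregations if s.variant == variant_id]

    def functionals_of(self, variant_id: str) -> list[FunctionalDatum]:
        return [f for f in self.functionals if f.variant == variant_id]

    def populations_of(self, variant_id: str) -> list[PopulationDatum]:
        return [p for p in self.populations if p.variant == variant_id]

    # -- validation --------------------------------------------------------

    def validate(self) -> None:
        """Check uniqueness and referential integrity across collections.

        Raises :class:`BundleIntegrityError` naming the offending record.
        """
        def check_unique(ids: list[str], what: str) -> None:
            seen: set[str] = set()
            for i in ids:
                if i in seen:
                    raise BundleIntegrityError(f"duplicate {what} id {i!r}")
                seen.add(i)

        check_unique([g.symbol for g in self.genes], "gene")
        check_unique([c.id for c in self.conditions], "condition")
        check_unique([v.id for v in self.variants], "variant")
        check_unique([c.id for c in self.cases], "case")
        check_unique([s.id for s in self.segregations], "segregation")
        check_unique([f.id for f in self.functionals], "functional")
        check_unique([p.id for p in self.populations], "population")

        genes = {g.symbol for g in self.genes}
        conds = {c.id for c in self.conditions}
        variants = {v.id for v in self.variants}

        generic_owner: dict[str, str] = {}
        for c in self.conditions:
            if c.is_generic:
                owners = [g for g in genes if c.id == generic_condition_id(g)]
                if not owners:
                    raise BundleIntegrityError(
                        f"generic condition {c.id!r} is not named from any gene symbol"
                    )
                owner = owners[0]
                if owner in generic_owner.values() and generic_owner.get(c.id) != owner:
                    raise BundleIntegrityError(
                        f"gene {owner!r} has more than one generic condition"
                    )
                generic_owner[c.id] = owner

        for g in self.genes:
            for cond_id, _kind in g.preliminary_links:
                if cond_id not in conds:
                    raise BundleIntegrityError(
                        f"gene {g.symbol}: preliminary link to unknown condition {cond_id!r}"
                    )
        for v in self.variants:
            if v.gene not in genes:
                raise BundleIntegrityError(
                    f"variant {v.id}: unknown gene {v.gene!r}"
                )
        for c in self.cases:
            if c.variant not in variants:
                raise BundleIntegrityError(f"case {c.id}: unknown variant {c.variant!r}")
            if c.condition not in conds:
                raise BundleIntegrityError(f"case {c.id}: unknown condition {c.condition!r}")
        for s in self.segregations:
            if s.variant not in variants:
                raise BundleIntegrityError(f"segregation {s.id}: unknown variant {s.variant!r}")
            if s.affected_condition not in conds:
                raise BundleIntegrityError(
                    f"segregation {s.id}: unknown condition {s.affected_condition!r}"
                )
        for f in self.functionals:
            if f.variant not in variants:
                raise BundleIntegrityError(f"functional {f.id}: unknown variant {f.variant!r}")
        for p in self.populations:
            if p.variant not in variants:
                raise BundleIntegrityError(f"population {p.id}: unknown variant {p.variant!r}")

    def generic_condition_of(self, gene_symbol: str) -> ConditionRecord | None:
        cid = generic_condition_id(gene_symbol)
        rec = self._condition_index.get(cid)
        if rec is not None and rec.is_generic:
            return rec
        return None


def record_fields(cls) -> list[str]:
    """Field names of a record dataclass, in declaration order."""
    return [f.name for f in dc_fields(cls)]
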