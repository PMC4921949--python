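"""Validity engine: proband counting, gene status, strengths, fixed point."""

import dataclasses

import pytest

from genevalidity import (
    BundleIntegrityError,
    CaseObservation,
    ConditionRecord,
    EvidenceBundle,
    GeneRecord,
    GeneStatus,
    SegregationDatum,
    FunctionalDatum,
    VariantRecord,
    assert_gene_condition,
    assess_gene,
    count_unrelated_probands,
    fixed_point_assess,
    generic_condition_id,
)
from genevalidity.engine import STRENGTHS
from genevalidity.synthetic import SyntheticConfig, generate_synthetic, proband_sweep_bundle

_SRANK = {s: i for i, s in enumerate(STRENGTHS)}


def _mini_bundle(n_probands, families=None):
    families = families or [f"F{i}" for i in range(n_probands)]
    return EvidenceBundle(
        genes=(GeneRecord("GENEX"),),
        conditions=(ConditionRecord("C1", "c1", frozenset({"AD"})),),
        variants=(VariantRecord("v1", "GENEX", "p.Gly10Ter", "nonsense"),),
        cases=tuple(
            CaseObservation(f"case{i}", "v1", f"P{i}", fam, "C1")
            for i, fam in enumerate(families)
        ),
    )


def _pathogenic_cls(bundle):
    from genevalidity.classifier import VariantClassification

    return {v.id: VariantClassification(v.id, "pathogenic")
            for v in bundle.variants}


def test_distinct_families_count_individually():
    b = _mini_bundle(3)
    assert count_unrelated_probands(b, _pathogenic_cls(b), "GENEX", "C1") == 3


def test_shared_family_counts_once():
    b = _mini_bundle(2, families=["F1", "F1"])
    assert count_unrelated_probands(b, _pathogenic_cls(b), "GENEX", "C1") == 1


def test_vus_only_gene_has_zero_probands(worked_bundle, worked_result):
    assert count_unrelated_probands(
        worked_bundle, worked_result.classifications, "SCN10A", "BRGDA") == 0


def test_unknown_gene_or_condition_is_lookup_error(worked_bundle, worked_result):
    with pytest.raises(BundleIntegrityError):
        count_unrelated_probands(
            worked_bundle, worked_result.classifications, "NOPE", "HCM")
    with pytest.raises(BundleIntegrityError):
        count_unrelated_probands(
            worked_bundle, worked_result.classifications, "MYH7", "NOPE")


def test_recessive_condition_ignores_het_and_unproven_partner_alleles(
        worked_bundle, worked_result):
    """JLNS probands: three homozygotes count; the compound het whose
    partner allele is a VUS does not; the 12 het LQTS carriers never do."""
    n = count_unrelated_probands(
        worked_bundle, worked_result.classifications, "KCNQ1", "JLNS")
    assert n == 3


def test_gene_proven_exactly_by_pathogenic_observed_variant(worked_bundle,
                                                            worked_result):
    assert assess_gene(worked_bundle, worked_result.classifications,
                       "MYH7").status == "proven"
    assert assess_gene(worked_bundle, worked_result.classifications,
                       "SCN10A").status == "uncertain"


def test_pathogenic_grade_evidence_without_cases_does_not_prove():
    """A variant can carry pathogenic-grade lab evidence, but without a
    clinically observed carrier the gene stays uncertain."""
    b = EvidenceBundle(
        genes=(GeneRecord("GENEX"),),
        conditions=(ConditionRecord("C1", "c1", frozenset({"AD"})),),
        variants=(VariantRecord("v1", "GENEX", "p.Gly10Ter", "nonsense"),),
        segregations=(SegregationDatum("s1", "v1", "F1", 4.0, "C1",
                                       family_count=3),),
        functionals=(FunctionalDatum("f1", "v1", "cellular",
                                     "loss_of_function",
                                     mechanism_concordant=True),),
    )
    res = fixed_point_assess(b)
    assert res.classifications["v1"].verdict == "pathogenic"
    assert res.statuses["GENEX"].status == "uncertain"


def test_gene_status_invariant():
    with pytest.raises(ValueError):
        GeneStatus("GENEX", "proven", proving_variants=())


# ------------------------------------------------------- strength thresholds


def test_proband_sweep_thresholds():
    """Strength of the swept link follows none / emerging / emerging /
    strong / strong ... exactly, out to k = 10."""
    expected = ["none", "emerging", "emerging"] + ["strong"] * 8
    got = [
        fixed_point_assess(proband_sweep_bundle(k)).strength("SWEEPG", "CONDB")
        for k in range(11)
    ]
    assert got == expected


def test_strength_monotone_in_probands():
    ranks = [
        _SRANK[fixed_point_assess(proband_sweep_bundle(k)).strength(
            "SWEEPG", "CONDB")]
        for k in range(8)
    ]
    assert ranks == sorted(ranks)


def test_suggested_requires_preliminary_link(worked_result):
    assert worked_result.strength("SCN10A", "BRGDA") == "suggested"
    # no preliminary link, no probands: no relationship at all
    assert worked_result.strength("SCN10A", "LQTS") == "none"


def test_generic_assertion_strong_iff_proven(worked_result):
    assert worked_result.strength("MYH7", generic_condition_id("MYH7")) == "strong"
    assert worked_result.strength(
        "SCN10A", generic_condition_id("SCN10A")) == "none"


def test_inconsistent_inputs_rejected(worked_bundle, worked_result):
    """A pathogenic classification map that contradicts itself (probands
    counted but no pathogenic variant recorded) cannot arise; the
    assertion constructor enforces the invariants directly."""
    from genevalidity import GeneConditionAssertion

    with pytest.raises(ValueError):
        GeneConditionAssertion("MYH7", "HCM", "strong",
                               unrelated_proband_count=5,
                               pathogenic_variants=())
    with pytest.raises(ValueError):
        GeneConditionAssertion("MYH7", "HCM", "suggested",
                               pathogenic_variants=("myh7_r403q",))


# --------------------------------------------------------------- fixed point


def test_empty_bundle_fixed_point():
    res = fixed_point_assess(EvidenceBundle())
    assert res.statuses == {} and res.assertions == ()


def test_fixed_point_iteration_bound(worked_bundle):
    res = fixed_point_assess(worked_bundle)
    assert res.n_iterations <= len(worked_bundle.genes) + 1


def test_gus_gene_has_no_strong_or_emerging_assertions(worked_result):
    for a in worked_result.assertions:
        if worked_result.statuses[a.gene].status == "uncertain":
            assert a.strength in ("suggested", "none"), a


def test_adding_unrelated_proband_never_decreases_strength():
    """Evidence monotonicity at the assertion level: a new unrelated
    pathogenic-variant proband can only hold or raise every strength."""
    for seed in range(5):
        bundle, _ = generate_synthetic(SyntheticConfig(
            n_proven_genes=2, n_gus_genes=2, seed=seed))
        before = fixed_point_assess(bundle)
        target = bundle.cases[0]
        extra = dataclasses.replace(
            target, id="extra_case", proband="P_EXTRA", family="FAM_EXTRA")
        grown = dataclasses.replace(bundle, cases=bundle.cases + (extra,))
        after = fixed_point_assess(grown)
        for a in before.assertions:
            assert (_SRANK[after.strength(a.gene, a.condition)]
                    >= _SRANK[a.strength]), (seed, a)


def test_ground_truth_recovery_sample():
    for seed in (0, 1, 2):
        bundle, truth = generate_synthetic(SyntheticConfig(seed=seed))
        res = fixed_point_assess(bundle)
        assert {g: s.status for g, s in res.statuses.items()} == truth.statuses
        for (g, c), want in truth.strengths.items():
            assert res.strength(g, c) == want


# ---------------------------------------------------- phenotype expansion


def test_expansion_flags_on_worked_examples(worked_result, worked_expected):
    for (g, c), want in worked_expected["expansion_flags"].items():
        assert worked_result.assertion(g, c).expansion_flag == want


def test_single_condition_gene_not_applicable(worked_result):
    assert worked_result.assertion("DMD", "DCM").expansion_flag == "not_applicable"
    assert worked_result.assertion("MYH7", "HCM").expansion_flag == "not_applicable"
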