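"""Criterion assignment, the combining table, modulation, monotonicity."""

import dataclasses

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from genevalidity import (
    BundleIntegrityError,
    ConditionRecord,
    EvidenceBundle,
    GeneRecord,
    VariantRecord,
    assign_criteria,
    classify_variant,
    combine_criteria,
    combine_criteria_table_scan,
    segregation_tier,
)
from genevalidity.classifier import CRITERION_CODES, PATH_TIERS, VERDICTS

_VRANK = {v: i for i, v in enumerate(VERDICTS)}  # benign .. pathogenic


@pytest.mark.parametrize(
    "lod, tier",
    [
        (3.4, "strong"),    # multi-family combined LOD of the HCM exemplar
        (3.0, "strong"),
        (2.99, "moderate"),
        (1.8, "moderate"),
        (1.5, "moderate"),
        (0.6, "supporting"),
        (0.59, "none"),
        (0.0, "none"),
        (-2.0, "none"),
    ],
)
def test_segregation_tiers(lod, tier):
    assert segregation_tier(lod) == tier


def test_segregation_tier_monotone_in_lod():
    order = ["none", "supporting", "moderate", "strong"]
    tiers = [order.index(segregation_tier(l / 10)) for l in range(-20, 60)]
    assert tiers == sorted(tiers)


def test_segregation_tier_rejects_non_finite():
    with pytest.raises(ValueError):
        segregation_tier(float("nan"))


# ---------------------------------------------------------------- criteria


def test_hcm_exemplar_criteria(worked_bundle):
    """Segregation and concordant functional evidence are strong, control
    absence is moderate — before any gene-level status is known."""
    crit = assign_criteria(worked_bundle, "myh7_r403q")
    by_kind = {c.kind: c for c in crit}
    assert by_kind["segregation"].code == "path_strong"
    assert by_kind["functional"].code == "path_strong"
    assert by_kind["functional"].modulated_from is None
    assert by_kind["absence"].code == "path_moderate"


def test_nonconcordant_functional_capped_with_provenance(worked_bundle):
    """A gain-of-function assay that does not establish the mechanism is
    down-weighted to supporting, and the cap is recorded."""
    crit = assign_criteria(worked_bundle, "kcnq1_v307l")
    fn = next(c for c in crit if c.kind == "functional")
    assert fn.code == "path_supporting"
    assert fn.modulated_from == "path_strong"


def test_case_count_uncapped_once_link_is_strong(worked_bundle):
    capped = assign_criteria(worked_bundle, "myh7_r403q")
    freed = assign_criteria(worked_bundle, "myh7_r403q",
                            link_strength={("MYH7", "HCM"): "strong"})
    cc_capped = next(c for c in capped if c.kind == "case_count")
    cc_freed = next(c for c in freed if c.kind == "case_count")
    assert cc_capped.code == "path_supporting"
    assert cc_capped.modulated_from == "path_moderate"
    assert cc_freed.code == "path_moderate"
    assert cc_freed.modulated_from is None


def test_variant_with_no_evidence_yields_no_criteria():
    bundle = EvidenceBundle(
        genes=(GeneRecord("GENEX"),),
        conditions=(ConditionRecord("C1", "c1"),),
        variants=(VariantRecord("v1", "GENEX", "p.Ala5Thr", "missense"),),
    )
    assert assign_criteria(bundle, "v1") == []


def test_unknown_variant_is_lookup_error(worked_bundle):
    with pytest.raises(BundleIntegrityError, match="unknown variant"):
        assign_criteria(worked_bundle, "no_such_variant")


def test_modulation_soundness(worked_bundle):
    """With every link strong and every assay mechanism-concordant, no
    criterion is ever down-weighted."""
    functionals = tuple(
        dataclasses.replace(f, mechanism_concordant=True)
        for f in worked_bundle.functionals
    )
    bundle = dataclasses.replace(worked_bundle, functionals=functionals)
    links = {
        (g.symbol, c.id): "strong"
        for g in bundle.genes for c in bundle.conditions
    }
    for v in bundle.variants:
        for crit in assign_criteria(bundle, v.id, link_strength=links):
            assert crit.modulated_from is None, (v.id, crit)


def test_classification_is_deterministic(worked_bundle):
    a = classify_variant(worked_bundle, "kcnq1_r518x")
    b = classify_variant(worked_bundle, "kcnq1_r518x")
    assert a == b


# ---------------------------------------------------------------- combining


@pytest.mark.parametrize(
    "criteria, verdict",
    [
        (["path_very_strong", "path_strong"], "pathogenic"),
        ([], "VUS"),
        (["benign_strong", "path_strong", "path_moderate"], "VUS"),  # conflict
        (["benign_standalone"], "benign"),
        (["path_strong", "path_moderate"], "likely_pathogenic"),
        (["path_moderate"] * 3, "likely_pathogenic"),
        (["benign_strong", "benign_supporting"], "likely_benign"),
        (["path_very_strong"], "VUS"),  # very strong alone is not enough
        (["path_strong", "path_supporting"], "VUS"),
    ],
)
def test_combining_table_rows(criteria, verdict):
    assert combine_criteria(criteria) == verdict
    assert combine_criteria_table_scan(criteria) == verdict


def test_malformed_criterion_code_rejected():
    with pytest.raises(ValueError, match="malformed"):
        combine_criteria(["path_extreme"])


@settings(derandomize=True, max_examples=400, deadline=None)
@given(st.lists(st.sampled_from(CRITERION_CODES), max_size=12))
def test_combiner_matches_table_scan(criteria):
    assert combine_criteria(criteria) == combine_criteria_table_scan(criteria)


@settings(derandomize=True, max_examples=400, deadline=None)
@given(
    base=st.lists(st.sampled_from(CRITERION_CODES), max_size=10),
    extra=st.sampled_from(CRITERION_CODES),
)
def test_combiner_monotone_under_added_evidence(base, extra):
    """Pathogenic-side evidence never moves a verdict toward benign, and
    benign-side evidence never moves it toward pathogenic."""
    before = _VRANK[combine_criteria(base)]
    after = _VRANK[combine_criteria(base + [extra])]
    if extra in PATH_TIERS:
        assert after >= before
    else:
        assert after <= before
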