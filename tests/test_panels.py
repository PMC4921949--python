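"""Panel composition, the differential, validity, and result guidance."""

import pytest

from genevalidity import (
    GeneConditionAssertion,
    PanelEntry,
    PanelSpec,
    YieldRow,
    classify_panel_gene,
    default_overlap_map,
    default_yield_table,
    design_panel,
    differential,
    fixed_point_assess,
    interpret_result,
    validate_panel,
)


@pytest.fixture(scope="module")
def overlap():
    return default_overlap_map()


@pytest.fixture(scope="module")
def worked_assertions(worked_result):
    return [a for a in worked_result.assertions if not a.is_generic]


def test_hcm_differential(overlap):
    assert differential("HCM", overlap) == {"HCM", "NOONAN_RAS", "FABRY"}


def test_dcm_differential(overlap):
    assert differential("DCM", overlap) == {"HCM", "DCM", "ARVD", "DMD_BECKER"}


def test_unknown_condition_is_lookup_error(overlap):
    with pytest.raises(KeyError):
        differential("LQTS", overlap)


def test_gene_classes(worked_assertions, overlap):
    assert classify_panel_gene("MYBPC3", "HCM", worked_assertions,
                               overlap) == "proven_for_condition"
    assert classify_panel_gene("SCN10A", "BRGDA", worked_assertions,
                               overlap | {"BRGDA": frozenset({"BRGDA"})}
                               ) == "suspected_for_condition"


def test_differential_class_requires_proven_link(overlap):
    """A gene strong for a differential condition is class 3; one merely
    suggested for the differential is excluded."""
    fabry_strong = [GeneConditionAssertion(
        "GLA", "FABRY", "strong", unrelated_proband_count=4,
        pathogenic_variants=("gla_v1",))]
    assert classify_panel_gene("GLA", "HCM", fabry_strong,
                               overlap) == "proven_for_differential"
    fabry_suggested = [GeneConditionAssertion("GLA", "FABRY", "suggested")]
    assert classify_panel_gene("GLA", "HCM", fabry_suggested, overlap) is None


def test_strongest_role_wins(overlap):
    """Strong for both the target and a differential condition: reported
    once, as proven for the target."""
    both = [
        GeneConditionAssertion("MYH7", "HCM", "strong",
                               unrelated_proband_count=5,
                               pathogenic_variants=("v",)),
        GeneConditionAssertion("MYH7", "FABRY", "strong",
                               unrelated_proband_count=3,
                               pathogenic_variants=("v",)),
    ]
    assert classify_panel_gene("MYH7", "HCM", both,
                               overlap) == "proven_for_condition"
    panel = design_panel("HCM", both, overlap)
    assert panel.genes == ("MYH7",)


def test_hcm_panel_composition(worked_assertions, overlap):
    panel = design_panel("HCM", worked_assertions, overlap)
    by_gene = {e.gene: e.gene_class for e in panel.entries}
    assert by_gene == {
        "FHL1": "proven_for_condition",
        "MYBPC3": "proven_for_condition",
        "MYH7": "proven_for_condition",
    }
    # DCM is not in the HCM differential: DMD is excluded here
    assert "DMD" not in by_gene


def test_dcm_panel_composition(worked_assertions, overlap):
    panel = design_panel("DCM", worked_assertions, overlap)
    by_gene = {e.gene: e.gene_class for e in panel.entries}
    assert by_gene["DMD"] == "proven_for_condition"
    # HCM genes enter through the differential (HCM can present as DCM)
    for g in ("MYH7", "MYBPC3", "FHL1"):
        assert by_gene[g] == "proven_for_differential"
    assert "KCNQ1" not in by_gene and "SCN10A" not in by_gene


def test_design_is_deterministic_and_duplicate_free(worked_assertions, overlap):
    p1 = design_panel("DCM", worked_assertions, overlap)
    p2 = design_panel("DCM", worked_assertions, overlap)
    assert p1 == p2
    assert len(set(p1.genes)) == len(p1.genes)


def test_empty_assertions_give_empty_panel(overlap):
    assert design_panel("HCM", [], overlap).entries == ()


# ------------------------------------------------------------- validation


def test_hcm_panel_requires_mybpc3(worked_assertions, overlap):
    table = default_yield_table()
    panel = design_panel("HCM", worked_assertions, overlap)
    without = PanelSpec("HCM", tuple(e for e in panel.entries
                                     if e.gene != "MYBPC3"))
    invalid = validate_panel(without, table)
    assert invalid.validity == "invalid"
    assert invalid.missing_required == ("MYBPC3",)
    assert validate_panel(panel, table).validity == "valid"


def test_removing_any_substantial_gene_flips_validity(worked_assertions,
                                                      overlap):
    table = default_yield_table()
    for target in ("HCM", "DCM"):
        panel = validate_panel(design_panel(target, worked_assertions,
                                            overlap), table)
        assert panel.validity == "valid"
        substantial = {
            r.gene for r in table
            if r.condition == target and (
                r.substantial or (r.yield_fraction or 0) >= 0.05)
        }
        assert substantial  # the fixture table flags genes for both targets
        for gene in substantial:
            pruned = PanelSpec(target, tuple(
                e for e in panel.entries if e.gene != gene))
            res = validate_panel(pruned, table)
            assert res.validity == "invalid" and gene in res.missing_required


def test_extra_suspected_genes_do_not_change_validity(worked_assertions,
                                                      overlap):
    table = default_yield_table()
    panel = design_panel("HCM", worked_assertions, overlap)
    padded = PanelSpec("HCM", panel.entries + (
        PanelEntry("NOVELGENE", "suspected_for_condition"),))
    assert validate_panel(padded, table).validity == "valid"


def test_yield_table_without_target_rows_is_config_error():
    with pytest.raises(ValueError, match="no rows"):
        validate_panel(PanelSpec("LQTS"), default_yield_table())


def test_yield_fraction_threshold_requires_gene():
    table = [YieldRow("SMALLG", "HCM", substantial=False, yield_fraction=0.06)]
    res = validate_panel(PanelSpec("HCM"), table)
    assert res.validity == "invalid" and res.missing_required == ("SMALLG",)


# ---------------------------------------------------------------- guidance


@pytest.mark.parametrize(
    "gene_class, verdict, guidance",
    [
        ("proven_for_condition", "pathogenic", "diagnostic_actionable"),
        ("proven_for_condition", "likely_pathogenic", "diagnostic_actionable"),
        ("proven_for_condition", "VUS", "segregation_studies_suggested"),
        ("proven_for_differential", "pathogenic", "expansion_or_incidental"),
        ("proven_for_differential", "VUS", "clinical_rereview_suggested"),
        ("suspected_for_condition", "pathogenic", "research_hold"),
        ("suspected_for_condition", "VUS", "research_hold"),
        ("proven_for_condition", "benign", "no_action"),
        ("suspected_for_condition", "likely_benign", "no_action"),
    ],
)
def test_result_guidance(gene_class, verdict, guidance):
    assert interpret_result(gene_class, verdict) == guidance


def test_panel_round_trip_through_engine(worked_bundle, overlap):
    """Re-running assessment and design from scratch reproduces the panel."""
    res = fixed_point_assess(worked_bundle)
    assertions = [a for a in res.assertions if not a.is_generic]
    p1 = design_panel("HCM", assertions, overlap)
    p2 = design_panel("HCM",
                      [a for a in fixed_point_assess(worked_bundle).assertions
                       if not a.is_generic], overlap)
    assert p1 == p2
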