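"""Random evidence-bundle generator with construction-time ground truth.

Each synthetic gene is built to a known intended outcome:

* a *proven* gene receives one proving variant whose evidence satisfies a
  pathogenic combining row without any modulation release (a strong
  segregation LOD plus a mechanism-concordant functional assay and
  control absence), observed in enough unrelated probands of the gene's
  condition to make the link strong;
* a *GUS* gene receives only VUS-profile variants (single case reports,
  control absence, in-silico support, sub-threshold segregation,
  non-concordant assays) plus a preliminary link, so its condition
  relationship is suggested and its status stays uncertain.

Generation is deterministic given the seed. The generator emulates the
shape of curated literature evidence, not its messiness: evidence
profiles are internally consistent, family ids are globally unique, and
phenotypes always match the recorded condition.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .evidence import (
    CaseObservation,
    ConditionRecord,
    EvidenceBundle,
    FunctionalDatum,
    GeneRecord,
    PopulationDatum,
    SegregationDatum,
    VariantRecord,
    generic_condition_id,
)

__all__ = ["SyntheticConfig", "GroundTruth", "generate_synthetic",
           "proband_sweep_bundle"]

_AA = ("Ala", "Arg", "Asp", "Cys", "Gly", "His", "Leu", "Met", "Pro", "Ser",
       "Thr", "Trp", "Tyr", "Val")


@dataclass(frozen=True)
class SyntheticConfig:
    """Shape of a generated bundle.

    ``evidence_mix`` gives the probabilities that a non-proving variant
    additionally carries a (weak) segregation, functional, or population
    record; the proportions must sum to at most 1.
    """

    n_proven_genes: int = 5
    n_gus_genes: int = 5
    probands_per_strong_link: int = 4
    variants_per_gene: tuple[int, int] = (1, 3)
    evidence_mix: tuple[float, float, float] = (0.3, 0.3, 0.3)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_proven_genes < 0 or self.n_gus_genes < 0:
            raise ValueError("gene counts must be non-negative")
        if self.probands_per_strong_link < 3:
            raise ValueError(
                "probands_per_strong_link must be >= 3 to realize an "
                "intended strong link"
            )
        lo, hi = self.variants_per_gene
        if not (1 <= lo <= hi):
            raise ValueError("variants_per_gene must be a range with 1 <= lo <= hi")
        if any(p < 0 for p in self.evidence_mix) or sum(self.evidence_mix) > 1:
            raise ValueError("evidence_mix proportions must be >= 0 and sum to <= 1")


@dataclass(frozen=True)
class GroundTruth:
    """Intended outcomes the assessment engine must recover."""

    statuses: dict[str, str] = field(default_factory=dict)
    strengths: dict[tuple[str, str], str] = field(default_factory=dict)


def generate_synthetic(
    config: SyntheticConfig = SyntheticConfig(),
) -> tuple[EvidenceBundle, GroundTruth]:
    """Generate a validated bundle plus its construction-time truth."""
    rng = np.random.default_rng(config.seed)

    genes: list[GeneRecord] = []
    conditions: list[ConditionRecord] = []
    variants: list[VariantRecord] = []
    cases: list[CaseObservation] = []
    segregations: list[SegregationDatum] = []
    functionals: list[FunctionalDatum] = []
    populations: list[PopulationDatum] = []
    truth_status: dict[str, str] = {}
    truth_strength: dict[tuple[str, str], str] = {}

    n_total = config.n_proven_genes + config.n_gus_genes
    fam_counter = 0

    def hgvs(i: int) -> str:
        a = _AA[int(rng.integers(len(_AA)))]
        b = _AA[int(rng.integers(len(_AA)))]
        return f"p.{a}{i + 10}{b}"

    for gi in range(n_total):
        proven = gi < config.n_proven_genes
        sym = f"SYNG{gi + 1:03d}"
        cond_id = f"COND{gi + 1:03d}"
        conditions.append(ConditionRecord(
            cond_id, f"synthetic condition {gi + 1}", frozenset({"AD"}),
            features=(f"feat_{cond_id}_a", f"feat_{cond_id}_b"),
        ))
        conditions.append(ConditionRecord(
            generic_condition_id(sym), f"{sym}-related conditions",
            is_generic=True))
        if proven:
            genes.append(GeneRecord(sym))
        else:
            genes.append(GeneRecord(
                sym, preliminary_links=((cond_id, "case_series_vus_only"),)))

        n_var = int(rng.integers(config.variants_per_gene[0],
                                 config.variants_per_gene[1] + 1))
        for vi in range(n_var):
            vid = f"{sym.lower()}_v{vi + 1}"
            proving = proven and vi == 0
            consequence = "nonsense" if proving else "missense"
            variants.append(VariantRecord(
                vid, sym, hgvs(int(rng.integers(50, 900))), consequence,
                computational_support=not proving))

            if proving:
                # pathogenic without modulation release: strong segregation
                # + mechanism-concordant functional + control absence
                fam_counter += 1
                segregations.append(SegregationDatum(
                    f"seg_{vid}", vid, f"SFAM{fam_counter}",
                    float(rng.uniform(3.0, 4.5)), cond_id,
                    family_count=int(rng.integers(2, 5))))
                functionals.append(FunctionalDatum(
                    f"fn_{vid}", vid, "cellular", "loss_of_function",
                    mechanism_concordant=True))
                populations.append(PopulationDatum(
                    f"pop_{vid}", vid, "synthetic-controls", 0,
                    int(rng.integers(20_000, 150_000))))
                for pi in range(config.probands_per_strong_link):
                    fam_counter += 1
                    cases.append(CaseObservation(
                        f"case_{vid}_{pi + 1}", vid, f"P{fam_counter}",
                        f"FAM{fam_counter}", cond_id,
                        phenotype_features=(f"feat_{cond_id}_a",
                                            f"feat_{cond_id}_b"),
                        severity="classic", onset="adult"))
            else:
                # VUS profile: one case report plus weak extras
                fam_counter += 1
                cases.append(CaseObservation(
                    f"case_{vid}_1", vid, f"P{fam_counter}",
                    f"FAM{fam_counter}", cond_id,
                    phenotype_features=(f"feat_{cond_id}_a",),
                    severity="classic", onset="adult"))
                p_seg, p_fn, p_pop = config.evidence_mix
                draw = rng.random()
                if draw < p_seg:
                    fam_counter += 1
                    segregations.append(SegregationDatum(
                        f"seg_{vid}", vid, f"SFAM{fam_counter}",
                        float(rng.uniform(0.0, 1.4)), cond_id))
                elif draw < p_seg + p_fn:
                    functionals.append(FunctionalDatum(
                        f"fn_{vid}", vid, "cellular", "loss_of_function",
                        mechanism_concordant=False))
                elif draw < p_seg + p_fn + p_pop:
                    populations.append(PopulationDatum(
                        f"pop_{vid}", vid, "synthetic-controls", 0,
                        int(rng.integers(20_000, 150_000))))

        truth_status[sym] = "proven" if proven else "uncertain"
        truth_strength[(sym, cond_id)] = "strong" if proven else "suggested"

    bundle = EvidenceBundle(
        genes=tuple(genes),
        conditions=tuple(conditions),
        variants=tuple(variants),
        cases=tuple(cases),
        segregations=tuple(segregations),
        functionals=tuple(functionals),
        populations=tuple(populations),
    )
    return bundle, GroundTruth(statuses=truth_status,
                               strengths=truth_strength)


def proband_sweep_bundle(k: int) -> EvidenceBundle:
    """Bundle for threshold sweeps: a proven gene with *k* unrelated
    probands of a second condition.

    The gene SWEEPG is proven through condition CONDA (a fully evidenced
    pathogenic variant in four unrelated probands); the same variant is
    additionally observed in ``k`` unrelated probands manifesting CONDB.
    The (SWEEPG, CONDB) strength therefore isolates the proband-count
    thresholds: none at 0, emerging at 1-2, strong from 3 on.
    """
    if k < 0:
        raise ValueError("k must be >= 0")
    sym, vid = "SWEEPG", "sweepg_v1"
    conditions = (
        ConditionRecord("CONDA", "anchor condition", frozenset({"AD"}),
                        features=("feat_a1", "feat_a2")),
        ConditionRecord("CONDB", "swept condition", frozenset({"AD"}),
                        features=("feat_b1", "feat_b2")),
        ConditionRecord(generic_condition_id(sym), f"{sym}-related conditions",
                        is_generic=True),
    )
    cases = [
        CaseObservation(f"case_a{i}", vid, f"PA{i}", f"FA{i}", "CONDA",
                        phenotype_features=("feat_a1", "feat_a2"),
                        severity="classic", onset="adult")
        for i in range(1, 5)
    ] + [
        CaseObservation(f"case_b{i}", vid, f"PB{i}", f"FB{i}", "CONDB",
                        phenotype_features=("feat_b1", "feat_b2"),
                        severity="classic", onset="adult")
        for i in range(1, k + 1)
    ]
    return EvidenceBundle(
        genes=(GeneRecord(sym),),
        conditions=conditions,
        variants=(VariantRecord(vid, sym, "p.Gly100Ter", "nonsense"),),
        cases=tuple(cases),
        segregations=(SegregationDatum("seg_sweep", vid, "FA1", 3.5, "CONDA",
                                       family_count=2),),
        functionals=(FunctionalDatum("fn_sweep", vid, "cellular",
                                     "loss_of_function",
                                     mechanism_concordant=True),),
        populations=(PopulationDatum("pop_sweep", vid, "controls", 0,
                                     100_000),),
    )
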