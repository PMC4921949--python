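# genevalidity

A deterministic rules engine for clinical-grade gene curation: variant
pathogenicity classification from structured evidence, gene–condition
clinical validity assertion, and diagnostic gene-panel design over
overlapping phenotypes.

Diagnostic laboratories reporting on multi-gene panels — particularly for
inherited cardiomyopathies and arrhythmias, where presentations overlap,
penetrance is incomplete, and dozens of genes carry anywhere from decades
of proof to a single case report — need a reproducible answer to three
questions: *is this variant pathogenic?*, *is this gene actually proven
to cause this condition?*, and *which genes belong on a panel for this
presentation?* `genevalidity` answers all three with one auditable
framework whose core insight is that gene-level validity reduces to
variant-level classification: a gene is proven to cause human disease
exactly when at least one clinically observed variant in it can be
classified pathogenic.

## The rules in brief

**Variants.** Evidence records (family segregation LOD scores, functional
assays, population allele counts, case observations, de novo status,
molecular consequence) are mapped to weighted criteria — pathogenic side
PVS/PS/PM/PP, benign side BA/BS/BP — and combined by a fixed table into
{pathogenic, likely pathogenic, VUS, likely benign, benign}. For example,
pathogenic requires PVS + ≥1 PS, or ≥2 PS, or PS + ≥3 PM, among other
rows; conflicting evidence on both sides yields VUS.

**Modulation.** Until a gene–condition relationship is established,
case-count and molecular-consequence evidence is down-weighted to
supporting, and functional evidence is strong only when the assay
demonstrates the disease-relevant mechanism. Segregation (LOD ≥ 3.0
strong) and confirmed de novo observations in severe early-onset disease
are never down-weighted — they are how a gene gets proven in the first
place.

**Genes and conditions.** A gene–condition relationship is *strong* with
≥ 3 unrelated probands carrying pathogenic variants and manifesting the
condition, *emerging* with 1–2 in an already-proven gene, *suggested* on
preliminary evidence alone. Classification needs link strengths and link
strengths need classifications; `fixed_point_assess` starts maximally
conservative and iterates to the (monotone, order-independent) fixed
point.

**Panels.** A panel for a condition holds genes proven for it, genes
suspected for it, and genes proven for its clinical differential; it is
valid only if every substantial-yield gene for the condition is present.

See `docs/methods.md` for the full rule set, thresholds, and rationale.

## Worked example

The package ships the evidence bundles for six classic cardiac curation
narratives (MYH7, KCNQ1, SCN10A, DMD, FHL1, MYBPC3):

```sh
genevalidity fixtures --worked --out fx/
genevalidity assess --bundle fx/worked_bundle.json \
    --out-matrix matrix.tsv --out-report report.json
```

prints the non-empty cells of the gene × condition strength matrix:

```
DMD     DCM     strong
FHL1    EDMD    strong
FHL1    HCM     strong
KCNQ1   JLNS    strong
KCNQ1   LQTS    strong
KCNQ1   SQTS    emerging
MYBPC3  HCM     strong
MYH7    HCM     strong
SCN10A  BRGDA   suggested
```

Reading it: MYH7–HCM is proven through p.Arg403Gln (four-family combined
LOD 3.4, concordant functional and animal-model data, absence from
controls). KCNQ1 is proven for two *distinct* conditions — recessive
Jervell–Lange-Nielsen syndrome and dominant long QT in heterozygous
carriers of the same founder allele — while its short-QT link is only
*emerging*: of the two reported variants, the confirmed de novo infantile
case classifies pathogenic but the single adult case report stays VUS:

```sh
$ genevalidity classify --bundle fx/worked_bundle.json --variant kcnq1_v307l
VUS
```

SCN10A, despite ~30 reported Brugada missense variants, has no
classifiable pathogenic variant (single cases, or common ExAC alleles),
so it remains a gene of uncertain significance with a *suggested* Brugada
link. The `report.json` carries proband counts, proving variants,
criterion-level provenance for every verdict, and phenotype-expansion
flags (KCNQ1 LQTS/JLNS → distinct conditions; FHL1 HCM/EDMD → complex
phenotype).

Panel design over those assertions:

```sh
$ genevalidity panel design --condition HCM --assertions report.json
FHL1    proven_for_condition
MYBPC3  proven_for_condition
MYH7    proven_for_condition
```

and `genevalidity panel validate` flags any panel missing a
substantial-yield gene (an HCM panel without MYBPC3 is invalid).

The library mirrors the CLI: `load_bundle`, `classify_variant`,
`fixed_point_assess`, `design_panel`, `validate_panel`,
`worked_examples`, `generate_synthetic`, all re-exported from
`genevalidity`.

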