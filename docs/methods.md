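# Methods

`genevalidity` implements a deterministic rules engine for three coupled
curation tasks in clinical molecular genetics: (1) classifying the
pathogenicity of individual sequence variants from structured evidence,
(2) deriving gene-level clinical validity and gene–condition strength
assertions from those classifications, and (3) composing and validating
condition-targeted diagnostic gene panels over overlapping clinical
presentations. The engine is built for inherited cardiomyopathies and
arrhythmias but nothing in the rules is cardiac-specific.

## The model

### Variant classification

Evidence about a variant is reduced to weighted criteria — pathogenic
side: very strong / strong / moderate / supporting; benign side:
stand-alone / strong / supporting — and combined by a fixed table into a
five-level verdict (pathogenic, likely pathogenic, VUS, likely benign,
benign). The combining rows are the conventional ones for this style of
framework, e.g. pathogenic requires one very strong criterion plus at
least one strong (or two moderate, or one moderate and one supporting, or
two supporting), or two strong, or one strong with enough moderate and
supporting criteria; likely pathogenic and the benign-side rows are
analogous; an empty or unmatched multiset is VUS.

**Conflict rule.** A side of the ledger is *active* once it either
matches a verdict row or holds strong-or-better evidence; if both sides
are active the verdict is VUS. The simpler "strong vs. strong" conflict
rule is a special case, but on its own it is not monotone: latent very
strong pathogenic evidence under a likely-benign verdict would let an
*added benign* criterion move the verdict toward pathogenic. The active-
side form restores the invariant that pathogenic-side evidence can only
move a verdict toward pathogenic and benign-side evidence only toward
benign, which the test suite enforces over randomized perturbations and
which the fixed-point iteration (below) relies on for convergence.

Criterion assignment from raw evidence:

* **Segregation** — combined log10 odds (LOD) across a variant's family
  sets, summed over records. Tiers: LOD ≥ 3.0 strong (the classical
  linkage significance bound), ≥ 1.5 moderate, ≥ 0.6 supporting.
  Segregation is direct statistical evidence and is never down-weighted.
* **Functional** — strong when any assay is flagged mechanism-concordant
  (it demonstrates the disease-relevant mechanism, with animal models
  folded in as an assay type); otherwise supporting, with the cap
  recorded. Assays showing no effect contribute supporting benign
  evidence.
* **Population** — allele frequency above 5×10⁻⁴ with at least 5 alleles
  in any cohort is strong benign evidence (appropriate for rare,
  dominant cardiac disease; configurable). Zero alleles across ≥ 10,000
  control alleles is moderate pathogenic evidence.
* **Case count** — ≥ 3 unrelated probands (distinct family ids)
  manifesting one specific condition is moderate evidence, down-weighted
  to supporting while that gene–condition link is unestablished.
* **De novo** — confirmed parentage in a severe, infantile- or
  childhood-onset phenotype is strong regardless of link status;
  confirmed parentage otherwise is moderate (supporting until the link
  is strong); assumed de novo is supporting.
* **Molecular consequence** — truncating classes (nonsense, frameshift,
  splice, exonic deletion) are very strong once some observed condition
  of the variant has a strong link to the gene (loss-of-function
  mechanism established), supporting until then; synonymous changes are
  supporting-benign.
* **Computational** — a pre-tagged supporting criterion; in-silico
  scores are never computed here.

Every down-weighting stores the original tier in `modulated_from`, so a
classification is a complete audit trail.

### Gene validity and condition strength

A gene is **proven** exactly when at least one *clinically observed*
variant (one with at least one case observation) classifies pathogenic.
A specific gene–condition relationship is **strong** at ≥ 3 unrelated
pathogenic-variant probands manifesting the condition, **emerging** at
1–2 such probands in a proven gene, **suggested** when only preliminary
evidence links the pair (a VUS-only case series, linkage, functional or
animal work), and absent otherwise. A gene with no strong relationship
is a gene of uncertain significance (GUS). Proven genes additionally
carry a strong assertion on the generic "<GENE>-related conditions"
entity; because a single de novo proband can prove a gene, the generic
assertion may legitimately hold fewer than three probands — the ≥ 3
invariant applies to specific conditions.

A case "manifests" a condition when its condition token matches, or when
at least 60% of the condition's feature tokens appear in the case's
phenotype features (configurable; this flat-token partial match stands in
for ontology reasoning, which is out of scope). For purely recessive
conditions, heterozygous observations never count, and a compound-het
proband counts only when every allele observed in that proband
classifies pathogenic. A multi-generation pedigree shares one family id
and counts once.

**Fixed point.** Classification depends on link strength (through the
modulation caps) and link strength depends on classification — a genuine
circularity. The engine initializes maximally conservatively (every gene
uncertain, every link unestablished) and iterates classify → assess →
re-link until the status and link maps stop changing. Strengthening a
link only raises criterion tiers, raising tiers only raises verdicts
(combiner monotonicity), and raising verdicts only raises counts and
links, so the update is monotone on a finite lattice: convergence is
guaranteed and the result is independent of evaluation order. Observed
bundles converge in 2–3 sweeps; the tests assert the `len(genes) + 1`
bound. Conservative initialization is escapable precisely because
segregation, mechanism-concordant functional, and severe-early confirmed
de novo evidence are never capped.

**Phenotype expansion.** For a gene with two or more at-least-emerging
specific conditions, the condition with the most probands is primary and
each other condition is flagged. `distinct_conditions` requires a
disjoint proband set *and* a different inheritance mode (the recessive
syndrome vs. dominant carrier phenotype pattern); it is checked first,
because a founder allele can legitimately appear in probands of both a
recessive syndrome and its heterozygous carrier condition without making
the phenotype "complex". Only then does a shared proband, shared variant,
or a case matching both feature sets mark `complex_phenotype`.

### Panels

A panel for a target condition contains genes proven for the target,
genes suspected (emerging/suggested) for it, and genes proven for a
condition in its clinical differential — the curated, editable overlap
map shipped in `data/overlap_cardiac.json` (presenting feature → set of
true underlying conditions). Precedence reports each gene once in its
strongest role, and merely-suggested links to a differential condition
never qualify. A panel is valid iff it contains every gene flagged
substantial for the target in the yield table (`data/yield_cardiac.tsv`;
a curated boolean plus an optional fraction with a 5% threshold — the
DMD–DCM fraction 0.08 reflects a published series of 34/436 isolated-DCM
males, the HCM fractions are illustrative defaults). Result guidance
maps (gene class, verdict) to clinical utility: actionable findings and
family segregation studies for proven genes, expansion-or-incidental and
clinical re-review for differential genes, research hold for suspected
genes, no action for benign-side verdicts.

## Worked examples and what they encode

`genevalidity.examples.worked_examples()` encodes six cardiac curation
narratives (MYH7 p.Arg403Gln; KCNQ1 p.Arg518*, p.Val307Leu, p.Val141Met;
SCN10A's Brugada missense set; DMD isolated-DCM; FHL1 isolated-HCM; a
MYBPC3 stub) together with the expected outcome table. Where the
narrative does not print an evidence tier, the fixture encodes the
minimal evidence forcing the narrated verdict and marks it SYNTHETIC in
the source: only MYH7's combined LOD of 3.4 is a published value; the
other LODs, assay records, cohort sizes, proband identities, and the
HGVS strings of the 30-variant missense set are stand-ins. The FHL1
frameshift individual is deliberately encoded with *assumed* (not
confirmed) de novo status: it classifies pathogenic only after the
FHL1–HCM link strengthens and uncaps its truncating-consequence
criterion, exercising the fixed-point interplay end to end.

## Synthetic generator

`generate_synthetic(SyntheticConfig(...))` builds random bundles with
construction-time ground truth. Defaults: 5 proven and 5 GUS genes, one
condition per gene, 1–3 variants per gene, 4 unrelated probands per
intended strong link, and a 30/30/30% chance that a non-proving variant
carries an extra weak segregation / non-concordant functional / control
absence record. A proven gene's proving variant holds a strong LOD
(uniform 3.0–4.5), a mechanism-concordant assay, and control absence —
pathogenic without any modulation release; GUS genes hold only
VUS-profile variants plus a preliminary link. Generation is fully
deterministic given the seed.

The generator emulates the *shape* of curated literature evidence, not
its messiness: profiles are internally consistent, families are globally
unique, phenotypes always match the recorded condition, and there is no
mislabeled or contradictory evidence. Passing the ground-truth recovery
property therefore shows the engine faithfully inverts its own rules
under clean evidence; it says nothing about robustness to curation error
or to evidence profiles near the tier boundaries, which the threshold
sweeps and perturbation properties probe separately.

## Numerical and procedural choices

* All thresholds live in `RunConfig` (YAML-overridable): LOD cuts
  3.0/1.5/0.6, benign frequency 5×10⁻⁴ with AC ≥ 5, absence cohort
  ≥ 10,000 alleles, case-count ≥ 3, phenotype match ≥ 0.6, strong link
  ≥ 3 probands, panel yield ≥ 0.05.
* The engine is fully deterministic: identical bundle and configuration
  give byte-identical outputs (iteration order is sorted; no timestamps
  in data outputs).
* Degenerate inputs: an empty bundle assesses to an empty result; a
  variant with no evidence gets no criteria and is VUS; a condition
  without feature tokens matches by id only; unknown ids raise lookup
  errors naming the id.
* Problem sizes in the default test run and the acceptance script:
  exhaustive combiner cross-check over all multisets with ≤ 5 of each of
  the 7 codes (6⁷ = 279,936 cases), 10,000 monotonicity perturbations
  (9,800 verdict-level, 200 end-to-end engine reruns), 50 synthetic
  recovery seeds, and proband sweeps to k = 10. These sizes exercise
  every rule boundary while keeping a full run in seconds.

## Limitations

* Condition identity is a flat token vocabulary with feature-set partial
  matching; no HPO/MONDO reasoning, no transcript-aware HGVS handling,
  no VCF input, and no in-silico predictor integration.
* Penetrance, onset and severity distributions, and mechanism annotation
  beyond the concordance flag are out of scope.
* The shipped overlap map and yield table are deliberately small, marked
  editable, and not comprehensive; real deployments should replace them
  with locally curated versions.
* The three-proband rule is a hedge against coincidence, not a
  statistical test; whether partial-phenotype probands should ever count
  toward strong is policy, exposed through the matching threshold.
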