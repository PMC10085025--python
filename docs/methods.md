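# Methods

This note documents the models implemented in `mitonuclear`, the defaults
and why they were chosen, what the synthetic-data generator does and does
not emulate, and the numerical decisions that affect reproducibility.

## Population simulator

**Founders.** A panel of `n_founders` haploids (default 25) is drawn from
`n_populations` ancestral populations (default 5) under a two-level
Balding–Nichols model: each marker has an ancestral allele frequency
p ~ U(0.1, 0.9) and each population draws its own frequency from
Beta(p(1−F)/F, (1−p)(1−F)/F), so the expected between-population variance
is F·p(1−p). The default differentiation F = 0.2 produces the clearly
structured panel that principal components must absorb in the scan.
Founders are assigned to populations round-robin and mating types
alternate, so every population carries both.

**Meiosis.** Crossovers follow a Haldane (no-interference, no obligate
crossover) model: along each chromosome, the gamete's allele origin is a
Markov chain whose switch probability between adjacent markers at map
distance d cM is r = (1 − e^(−2d/100))/2; chromosomes segregate
independently (switch probability ½ at each chromosome start). This is the
simplest crossover model consistent with a bp+cM marker map; interference
would mildly reduce double-crossover rates at short scales but does not
affect the statistical structure the scan relies on.

**Intercross.** Each round pairs random MATa × MATα individuals and keeps
`progeny_per_round` meiotic products. The mating-type locus is modelled as
a designated marker (default: mid-chromosome 3); a gamete is MATa exactly
when it inherited that region from its MATa parent, so progeny mating
types segregate ~1:1 without being imposed. After the final round
(default 7), `sample_size` haploids (default 181) are drawn without
replacement and replicated across the mitotype labels (default RC1/RC2/RC3
— isonuclear replication, the defining feature of the collection design).
Founder-ancestry tracks are carried per marker so ancestry uniformity and
LD decay are directly auditable. Marker-assisted selection steps that real
collection construction may use are not simulated; they would perturb
allele frequencies only near the selected markers.

**Default genome.** 16 chromosomes × 1,560 evenly spaced markers
(≈25,000 biallelic sites) over 750 kb per chromosome at 0.4 cM/kb. The
replicated simulation studies shipped with the package (`study_config`)
run on a reduced grid of 16 × 75 markers with 1,000 progeny per round —
the collection-level quantities (sample sizes, mitotypes, founder number,
rounds, colony counts) are kept at their defaults while the marker count
and intercross census are scaled so that 20-replicate studies finish in
tens of seconds; marker density and census size affect LD resolution, not
the per-SNP sampling distributions the studies measure.

**Phenotype model.** Effects live on the log-odds (logit) scale of the
per-colony petite probability: baseline μ (default logit(0.05), i.e. 5%
petite), nuclear main effects β per SNP, mitotype effects, SNP×mitotype
interaction effects δ expressed in a single mitotype, and covariate
effects. Counts are Binomial(n, expit(η)) with n = 500 colonies per assay
by default; overdispersion ≥ 1 is implemented exactly by beta-mixing the
probability with shape s = (n−1)/(φ−1) − 1, which inflates the count
variance by precisely φ. `plant_architecture` places requested loci among
markers with observed MAF near a target (default 0.3 ± 0.07), on distinct
chromosomes where possible, and at least 25 kb from chromosome ends so
planted loci survive telomere masking.

**Seed discipline.** A master seed spawns per-stage streams via
`SeedSequence([master, crc32(stage_name)])`; any stage can be re-run in
isolation and reproduce byte-identically.

## SNP table filters

Filters apply in a fixed order with before/after counts recorded:
(1) runs of variants at consecutive base positions merge into a single
record keyed by the leftmost position with concatenated allele labels —
each strain's merged call is its haplotype over the run, so discordant
runs become multiallelic and fall to the next filter; (2) variants within
`telomere_mask_bp` (default 20,000 bp — "telomeric" is not a standardised
distance, so it is configurable) of either chromosome end are dropped;
(3) only biallelic records are kept; (4) variants with MAF below the
threshold are dropped, with missing calls excluded from the frequency
denominator and the boundary value kept. The MAF default is 0.05;
published pipelines for comparable data report thresholds between 0.5%
and 5%, so the value is a required, reported configuration item rather
than a constant. Coordinates are 1-based inclusive throughout.
Missing/deletion calls are treated as missing, not as an allele class.

## Phenotype estimators

- Petite frequency: 100 × petite/total per assay; the strain-level
  phenotype for the Gaussian scan is the mean over replicate assays.
  Pooled counts are retained for the binomial scan, and an empirical-logit
  response log((k+½)/(n−k+½)) is provided (below).
- Vmax: the maximum OLS slope over sliding windows of 5 consecutive OD600
  readings, using actual time stamps so missing readings do not inflate
  slopes. The analytic check: a noiseless logistic K/(1+e^(−r(t−t0)))
  sampled every 15 min yields Vmax within 2% of rK/4.
- Colony growth proxy: max − min replicate colony size (unit-agnostic).
- qPCR relative expression: residuals of 1/Ct(candidate) regressed on
  1/Ct(control) across samples; higher residual = more starting template.
  The proportional-expression identity (all residuals 0) holds exactly
  only for equal expression; for a constant fold change the 1/Ct
  relationship is mildly nonlinear, though negligibly so over realistic
  Ct ranges.

## Association scan

Per SNP, three nested fits (M0 covariates+mitotype; M1 +SNP;
M2 +SNP×mitotype). How a single fitted interaction model should yield
separate "main" and "interaction" p-values is underdetermined; nested
model comparison was chosen because it is well defined for a 3-level
mitotype factor and invariant to reference coding. The Gaussian family
tests with F statistics using the fuller model's error term (matching
`anova()` on nested linear models); the binomial family uses χ²
likelihood-ratio tests on (petite, grande) counts. Rank changes are
detected via least-squares rank (Gaussian) or pivoted-QR column pruning
(binomial): a SNP adding no rank is flagged `collinear`; an interaction
block adding fewer than (levels−1) columns — e.g. an allele absent from
one mitotype — is tested at reduced df and flagged `reduced_df`;
monomorphic SNPs get undefined p-values. Strains missing a call at a SNP
are dropped for that SNP only (complete case). Near-zero residuals from
saturated noiseless fits resolve deterministically: statistic 0 / p = 1
when the nested reduction is also ~0, else an effectively infinite
statistic.

**Response scale.** The default response is the strain-mean petite
percentage. When effects are multiplicative (logit-scale, as in the
generator), two caveats matter. First, a strong logit-additive main effect
is *genuinely* non-additive on the percent scale once mitotypes differ in
baseline — expit curvature turns it into a real percent-scale interaction,
which the Gaussian scan then correctly reports. Second, the binomial χ²
LRT assumes the model contains every systematic effect; unmodelled loci
create extra-binomial dispersion that inflates all tests (in a pilot with
three δ = 1.5 loci unmodelled, most null SNPs reached nominal
significance). The replicated simulation studies therefore use the
Gaussian scan on the empirical-logit response, which matches the
generative scale, keeps the main-effect locus null in the interaction
test, and absorbs residual heterogeneity into the error variance the way
a linear model on strain means does. With small effects — the regime of
real data — the three responses give closely similar answers.

**Covariates and conditioning.** PCA runs on the unique nuclear genotypes
(mean-imputed per variant, centered, optional 1/√(p(1−p)) scaling), scores
broadcast to mitotype replicates; the default k = 10 components is
configurable. Mating type and auxotrophy flags enter as factors.
Conditioning SNP genotypes (e.g. a large-effect mtDNA-polymerase locus)
append to the covariates; conditioning removes their variance from the
residual and measurably raises interaction-test power — the package's
conditioning study (one β = 2 locus, five δ = 0.5 loci, 543 rows) shows
the mean count of interaction hits at q < 0.05 rising from ~0 to ~12.

**Multiple testing.** Bonferroni (per-test threshold α/m; at α = 0.05 over
24,955 SNPs this is 2.0 × 10⁻⁶), Benjamini–Hochberg, and Storey q-values.
π₀ is estimated as a cubic polynomial smoother through
π₀(λ) = #{p > λ}/(m(1−λ)) over λ ∈ {0.05, …, 0.90}, evaluated at λ = 0.90
and clipped to [1/m, 1]; fixing π₀ = 1 reproduces BH exactly, which the
tests assert. Default reporting thresholds: FDR 0.1% for main effects,
5% for interactions, both configurable.

**Effect size.** Δ = |f₀·p̄₀ − f₁·p̄₁| with allele frequencies over
non-missing calls and p̄ the mean strain petite frequency per allele
class, in percent; undefined (NaN) for monomorphic SNPs.

**Pairwise epistasis.** For each (SNP, focal SNP) pair on a
single-mitotype collection, an F-test of additive vs additive+product;
self-pairs and perfect-LD pairs are flagged and excluded, with BH
q-values over tested pairs.

## Annotation

A SNP maps to a gene if inside any CDS interval or within 250 bp
(end-inclusive, configurable) upstream of the CDS start — the translation
start, measured on the gene's strand — and may map to multiple genes.
Non-synonymous classification (which needs sequence + phase) is out of
scope; the CDS-or-upstream rule is the operative filter. Significant SNPs
collapse into QTLs by single-linkage merging within 25 kb (roughly the LD
scale expected after seven intercross generations); the peak SNP is the
minimum-p member, every input SNP belongs to exactly one QTL, and
intervals on a chromosome are disjoint.

## mtDNA features

GC% counts G+C over unambiguous bases only. GC-cluster counting scans both
strands for library motifs within a Hamming tolerance (default 2
mismatches); a forward match and its reverse complement at the same locus
count once (the elements are palindromic), and overlaps resolve greedily
left-to-right with deterministic tie-breaking (fewer mismatches, then
class label). Real cluster-class definitions come from curated homology
alignments and are supplied by the user as FASTA/TSV; the bundled
`example_motif_library` is synthetic — nine deterministic 32-bp
palindromic GC-rich motifs kept mutually distant so that round-trip tests
(plant k instances, recover exactly k) are unambiguous. Feature–phenotype
association uses Pearson r with the two-sided p from
t = r√(n−2)/√(1−r²) on n−2 df, cross-checked against a permutation null
in the tests; zero-variance features are flagged rather than crashing.

The mtDNA generator writes an AT-rich i.i.d. backbone (default 5% GC) and
overwrites non-overlapping random segments with the requested motif
instances (≥1 bp apart), preserving total length. It does not model
introns, genes, or the length/GC correlation structure of real mtDNAs; it
exists so the detector has a ground truth.

## What the simulation studies do and do not show

Passing the shipped studies demonstrates that the scan is calibrated under
the null (interaction type-I error ≈ 5% on 543 rows), that it recovers
δ = 1.5 logit interaction loci at MAF ≈ 0.3 essentially always at n = 543
with 500-colony assays, that a logit-additive main effect does not leak
into the interaction test on the matched response scale, and that
conditioning on a large-effect locus increases interaction-mapping power.
It does not demonstrate robustness to features the generator omits: strain
relatedness beyond the intercross design, genotyping error, structural
variation, assay batch effects, heteroplasmy, or selection during
collection construction. Real-data effect sizes and hit counts depend on
the trait architecture and cannot be anticipated from these studies.

## Known limitations

- No kinship/mixed-model correction; population structure is handled by
  principal components only.
- The binomial χ² scan is anti-conservative under unmodelled
  heterogeneity (see Response scale); use it when the model is believed
  complete or effects are small.
- No genotype imputation; per-SNP complete-case analysis.
- QTL grouping is positional single-linkage, not LD-based fine-mapping.
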