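# Methods

This note documents the models, procedures and numerical choices behind
`snptrace`, and what the synthetic-data generator does and does not emulate.

## Problem setting

Forensic traceability of trafficked wildlife requires assigning a sample of
unknown origin to a *source population*, not just a species. `snptrace`
implements a fixed-allele strategy: delineate genetically distinguishable
populations from genome-wide SNPs, find sites where one population is
(nearly) fixed for one allele while every other population is fixed for the
opposite allele, and wrap those sites in short PCR amplicons so they can be
typed from degraded material by Sanger sequencing. An mtDNA haplotype-network
module quantifies why the traditional mitochondrial approach under-resolves
closely related populations.

## Variant filtering

Input is a multi-sample diploid VCF. Two per-site filters are applied, in
either order (they commute):

- **Quality hard filters.** A site is removed iff any of
  `QD < 2.0`, `MQ < 40.0`, `FS > 60.0`, `HaplotypeScore > 13.0`,
  `MQRankSum < -12.5`, `ReadPosRankSum < -8.0` holds. Inequalities are
  strict; a site whose annotation is absent passes that sub-filter (an
  unevaluable expression cannot trigger removal — the behaviour of the
  standard variant-filtration tools these thresholds come from).
  `HaplotypeScore` is treated as optional: modern haplotype-based callers no
  longer emit it.
- **Frequency filters.** Retain sites with minor-allele frequency >= 0.05
  and call rate >= 0.9, both boundaries inclusive (vcftools semantics). MAF
  denominators count non-missing alleles only.

Multiallelic records are split into biallelic records by default (genotype
alleles referring to a different alternate become missing in each split
record); a `drop` policy is available. Coordinates are 1-based closed at the
VCF/GFF surface and converted to 0-based half-open only inside slicing code.

## Population structure

- **IBS kinship.** For two diploid genotypes the per-site identity-by-state
  fraction is (shared alleles)/2, i.e. {0, 0.5, 1}; raw kinship is the mean
  over sites where both samples are called. "Normalized" kinship min-max
  rescales the matrix so the smallest off-diagonal value maps to 0 and
  self-similarity to 1; the raw matrix is always reported alongside, since
  the normalization is a display convention, not a model.
- **PCA.** Genotypes are coded as 0/1/2 alternate-allele dosage,
  mean-imputed per site for missing calls, column-centered (optional
  p(1-p) scaling), then decomposed by SVD. Variance fractions are
  eigenvalues over total variance.
- **Patterson's D.** Per-population derived-allele frequencies f1..f3 and
  the outgroup f4 give `ABBA = sum (1-f1) f2 f3 (1-f4)` and
  `BABA = sum f1 (1-f2) f3 (1-f4)`; `D = (ABBA-BABA)/(ABBA+BABA)`.
  Polarization takes the outgroup's major allele as ancestral; sites where
  the outgroup minor-allele frequency exceeds 0.1 (configurable) are
  skipped, as are sites where any population is entirely uncalled.
  Significance comes from a delete-one block jackknife over contiguous site
  blocks (default 1000 sites; small datasets should lower it so that at
  least ~20 blocks exist). Note that D tests the *arrangement*
  (((P1,P2),P3),O): arranging a true sister pair across the P1/P3 positions
  yields D != 0 from shared drift alone. That is treeness, not gene flow,
  and it is why the calibration test uses tree-concordant trios only.
- **f4-ratio.** `alpha = f4(A,O;X,C) / f4(A,O;B,C)` with
  `f4 = sum (pA-pO)(pX-pC)` estimates the B-derived ancestry fraction of an
  admixed X, assuming A is an unadmixed B-side reference and C the other
  source's relative. Reported with numerator and denominator; a zero
  denominator flags the result undefined.

## Gene screening

Markers are restricted to genes whose local genealogy tracks the species
tree, reducing the risk that a "diagnostic" allele reflects a discordant
gene history (incomplete lineage sorting, introgression):

1. keep genes whose longest transcript (exon-length sum) strictly exceeds
   2000 bp;
2. build a per-sample consensus of the longest transcript: reference exons
   concatenated in genomic order, homozygous alternate SNPs substituted,
   heterozygous sites written as IUPAC ambiguity codes, indels skipped,
   minus-strand transcripts reverse-complemented;
3. build a neighbor-joining gene tree on pairwise p-distance, with
   ambiguous/N positions excluded from each pair's denominator (so
   heterozygosity does not inflate distances by arbitrary allele choice);
4. compute the Robinson-Foulds distance — the count of non-trivial
   bipartitions present in exactly one tree, after pruning both trees to
   their shared leaf set — against a species tree supplied as Newick or
   built by NJ on the concatenated screened transcripts;
5. rank genes by RF (ties broken by longer transcript, then gene id) and
   select the lowest quantile (default 0.25, boundary ties included) or an
   absolute RF cutoff as *target genes*.

NJ replaces likelihood tree inference deliberately: the screening signal is
topological concordance, NJ is deterministic and fast at this scale, and an
import hook accepts externally computed Newick gene trees when likelihood
trees are preferred. The package also reports the Pearson correlation
between transcript length and RF distance with its t-distribution p-value.

## Diagnostic sites, amplicons, primers, assignment

- **HAF.** The homozygous allele frequency of allele *a* in population *P*
  is the fraction of P's genotyped members homozygous for *a*. Missing
  individuals are excluded from the denominator (a stricter all-individuals
  denominator is available).
- **Screen.** A biallelic site is diagnostic for focal population P iff
  `HAF_P(a) >= t` and `HAF_Q(b) >= t` for every other population Q, where b
  is the opposite allele. One global threshold t per run; presets 1.0, 0.9
  and 0.8 reflect decreasing population differentiation. Sites where any
  population has no genotyped member are skipped, since the opposite-
  fixation intersection cannot be evaluated there.
- **Gene gating.** With an annotation, sites are attached to genes by exon
  overlap and kept only inside target genes; without one, sites pass
  through ungated (the path used for taxa lacking a genome annotation).
- **Amplicons.** 900 bp of flanking sequence on each side of the site gives
  a 2x900+1 = 1801 bp window; sites within 900 bp of a contig end are
  skipped, never truncated.
- **Primers.** Candidate primers are enumerated on both strands inside the
  window with size in [20, 26] (optimum 22), Tm in [52, 62] C (optimum 56),
  GC in [30, 70]% (optimum 50), product size 150-900 bp spanning the site,
  pair Tm difference <= 5 C, and a simple 4-base 3'-complementarity
  exclusion. Tm uses nearest-neighbor thermodynamics (SantaLucia 1998
  table, 50 mM monovalent salt, 250 nM primer). Pairs are ranked by
  weighted deviation from the optima plus Tm mismatch; deeper
  secondary-structure screening is out of scope.
- **Marker ranking.** Final per-population marker choice is deterministic
  (target-gene membership, then largest opposite-fixation margin, then
  smallest coordinate) rather than by-eye shortlist selection.
- **Assignment.** A sample matches a marker when homozygous for the focal
  allele; the per-population score is the matched fraction of typed
  markers, and the call requires a strictly highest score >= 0.8 (default).
  Heterozygous genotypes never match, so F1 hybrids score 0 everywhere and
  come back "unassigned" — hybrid screening with D statistics is
  recommended before panel typing.

The pipeline's screened diagnostic-site list is reported in full; the
gene-gated, primer-bearing marker table (Pop / Gene / Mutation / Left
Primer / Right Primer) is the forensic deliverable.

## mtDNA haplotype networks

Aligned mitogenomes are collapsed into haplotypes under a comparable-column
rule: two sequences are the same haplotype iff they agree at every column
where neither has a gap or N (differences hidden behind missing data never
split haplotypes; the merge is greedy in input order because the relation is
not transitive under missingness). The network is a minimum spanning
network over pairwise mutation steps: Kruskal by weight tier, adding *all*
edges of a tier that join components distinct before that tier, so
co-minimal alternatives are retained. Median vectors (inferred
intermediates) are not inserted — resolution conclusions need only the
sharing structure. The resolution report flags a population traceable iff
all of its individuals carry haplotypes private to it.

## Synthetic data generator

`simdata` generates the study conditions every module is tested against:

| parameter | default | meaning |
|---|---|---|
| n_pops x samples_per_pop | 3 x 8 | populations in two clades ((1,2),3) |
| contig_length | 60 kb | single annotated chromosome |
| n_genes / n_target_genes | 6 / 2 | 4 long (2.4 kb transcript) + 2 short (1.2 kb) genes; planted sites live in the first 2 long genes |
| n_planted_per_pop | 10 | fully fixed diagnostic differences (focal HAF 1.0, opposite fixation elsewhere) |
| n_background_sites | 2000 | drifted SNPs, ancestral MAF U(0.05, 0.5) |
| clade_fst / pop_fst | 0.15 / 0.05 | Balding-Nichols drift intensities |
| outgroup_fst | 0.2 | outgroups are separate species: strongly drifted, nearly fixed at ingroup-polymorphic sites |
| missing_rate | 0.02 | applied to background genotypes only — forensic markers are chosen to type reliably, so planted sites stay complete |
| exon_background_fraction | 0.2 | purifying selection thins background SNP density in exons, which is also what gives planted genes their concordance advantage |
| mt_len | 16,545 bp | realistic mitogenome alignment length |
| mt haplotypes | 2 per population, one shared pair (pop2, pop3) | emulates mtDNA's limited resolution |

Construction guarantees, relied on by tests: planted sites sit inside
target-gene exons at >= 900 bp from contig ends (amplicon extraction never
hits the skip path); every background site retains at least one called
heterozygote, so no background site can pass an opposite-fixation screen at
t = 1.0; all outputs are bit-exact functions of (seed, config).

What the generator does *not* emulate: genealogical noise (it is a
site-independent frequency model — no linkage, recombination, or coalescent
variance), sequencing error, allele dropout in degraded samples, indels,
and unsampled "ghost" populations. Passing tests therefore demonstrate the
correctness of the screening/assignment machinery under the stated
population model, not field performance on real forensic material.

## Problem sizes and determinism

Test and acceptance runs use desk-scale sizes chosen to exercise every code
path: 100 random instances (<= 20 samples x 200 sites) for the exhaustive
diagnostic-screen cross-check, 200 random tree pairs (<= 10 leaves) for the
RF cross-check, 6000 background sites with introgression fraction 0.5 for
the gene-flow benchmark (block jackknife at 200 sites/block, ~9-30 usable
blocks), and 100 assignment replicates. All randomness flows through
numpy's `default_rng` seeded explicitly; reruns are byte-identical.

## Known limitations

- Fixed-allele panels cannot represent unsampled populations; samples from
  outside the reference set will either be unassigned or misassigned.
- The HAF screen counts sites over the filtered biallelic SNP universe;
  published fixed-site counts from other universes (e.g. including
  invariant or unfiltered sites) are not directly comparable.
- Primer Tm is a thermodynamic model with fixed salt/primer concentrations;
  wet-lab conditions differing from 50 mM Na+ / 250 nM primer shift Tm.
- NJ gene trees can differ from likelihood trees on low-signal genes; the
  import hook exists for exact parity with likelihood workflows.
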