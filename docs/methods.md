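# Methods

This note records the models, conventions and design choices behind
`ionprior`, the assumptions they rest on, and what the package's tests do
and do not demonstrate about real diagnostic data.

## Variant identity and normalization

All reasoning about variants — consensus counting, frequency and clinical
lookups, compound-het detection, truth matching — uses the canonical key
`(chrom, pos, ref, alt)` of a biallelic, parsimonious, left-aligned
representation. Multiallelic records are first decomposed (one output per
alt; genotype alleles pointing at other alts are mapped to the reference
allele for that output, missing stays missing). Each single-alt record is
then iteratively right-trimmed / left-extended / left-trimmed against the
reference: while ref and alt share their last base, drop it, first
prepending the preceding reference base whenever an allele would become
empty; finally strip shared leading bases while both alleles keep at
least one (the VCF anchor-base convention: one shared leading base
remains for indels rather than zero-length alleles). A `max_shift` cap
(default 1000 bp) bounds the leftward scan; exceeding it raises an error
rather than stopping silently. At position 1 of a contig no left
extension is possible and a right-anchored form is accepted as canonical.

Correctness is established against a brute-force oracle that enumerates
every haplotype-equivalent `(pos, ref, alt)` in a window, filters to
parsimonious representations, and picks the one at minimal position; the
implementation matches it on thousands of randomized indels in repetitive
contexts, and independently agrees with `bcftools norm` on generated
VCFs. Complex block substitutions are normalized but not re-decomposed
into SNV primitives.

## Consensus

The six-caller ensemble is emulated, not wrapped: the module consumes
per-caller VCFs. A site counts as called by a caller when that caller
emitted it with FILTER PASS (non-PASS records are retained with a flag
and can be counted via `count_nonpass`) and at least one sample carrying
the alt allele. Keys supported by fewer than `min_support` callers are
dropped. The default `min_support = 2` balances tolerance of single-
caller dropout against caller-private false positives; it is exposed as
a parameter and a CLI flag since any consensus policy should be
auditable. Callers that produced no VCF for a sample reduce the number
of callers run rather than counting as negative votes. Genotypes are
reconciled per sample by majority vote over het vs hom-alt calls, ties
broken by a fixed caller-priority order (the ensemble's listing order);
hom-ref and missing calls do not vote.

## Consequence annotation

Transcript models are minimal: ordered exons, strand, a fully coding CDS
(the packaged toy models carry no UTRs; exonic positions outside a
user-supplied CDS would be reported as intronic — a documented
limitation, as UTR classes are out of scope). SNVs in the CDS are
classified by rebuilding the affected codon and translating with the
standard genetic code (reverse-complemented internally on the minus
strand): stop-gain → nonsense, amino-acid change → missense, silent →
synonymous; stop-loss is folded into missense. Coding indels are
frameshift when net length change is not divisible by 3, otherwise
in-frame. Any edit touching the two canonical intronic bases flanking an
exon–intron junction is a splice variant and overrides other classes;
the window is configurable (`--splice-window`, default ±2 bp) because
splice-region definitions vary between laboratories. Deep-intronic
positions beyond the panel's padded design regions receive no gene
assignment. Protein changes are simplified `p.<ref><codon><alt>` strings,
not full HGVS. The loss-of-function predicate is
`{nonsense, frameshift, splice}`.

Pre-computed in-silico predictor scores (SIFT, PolyPhen2, ...) may ride
along in the clinical table but the decision logic never conditions on
them: the tier ladder uses only reportedness, consequence class, and MAF.

## Prioritization cascade

Mode-specific rarity thresholds are strict inequalities: dominant
candidates pass with MAF < 1e-4, recessive with MAF < 5e-3; a variant
absent from the frequency table passes both (absence from population
databases is evidence of rarity, not missingness of the pipeline).
"Novel" means unreported in the clinical table; variants catalogued as
benign never qualify, and variants catalogued as VUS are neither
reported-pathogenic nor novel, so in known genes they do not tier.

Tiers: T1 reported pathogenic / likely pathogenic in a known gene, T2
novel LoF in a known gene, T3 novel missense in a known gene, T4 any
qualifying variant in a candidate-status gene (emitted as
`vus_candidate`, not as solved). A recessive explanation requires a
biallelic pattern — one homozygote or two distinct heterozygotes — and
its tier is the weaker of its two alleles' tiers, since the explanation
stands only if both alleles qualify. Phase is unknown: two heterozygotes
are presumed compound-heterozygous unless a genotyped parent carries
both, which refutes the trans configuration.

Within one gene, when both a monoallelic-dominant and a biallelic-
recessive explanation are constructible (possible in the four both-mode
genes OPA1, WFS1, ACO2, SPG7), the biallelic explanation wins and the
gene's monoallelic candidates are withdrawn — a biallelic qualifying
genotype explains the phenotype more completely — and the case is
flagged `both_modes_constructible`. Across genes, candidates are ranked
by tier, then segregation status (consistent < untested < inconsistent),
then biallelic before monoallelic, then gene symbol; equal-ranked
competing genes are flagged `ambiguous_gene`. A single heterozygote in a
recessive-only context leaves the case unsolved with a
`monoallelic_recessive_hit` flag rather than guessing carrier status.

Dominant segregation is strict by default (no unaffected carriers);
`allow_unaffected_carriers` relaxes this for incomplete penetrance.

## Coverage QC

Coverage fractions are the share of panel design bases with depth
strictly above each threshold (25/50/100×); a flag switches to ≥ since
the notation ">25×" is ambiguous in routine reports. The three
thresholds are computed as independent statistics. Backfill regions are
maximal runs of design bases at or below a depth floor (design bases
missing from the track count as depth 0), labeled with gene and exon for
Sanger follow-up.

## Synthetic cohort generator

The generator is the package's stand-in for a clinical cohort that is
not publicly deposited. Its defaults are the published study conditions:
1,102 probands; 245 solved (186 dominant, 59 recessive); dominant cases
drawn per gene as OPA1 76, ACO2 31, WFS1 23, MFN2 11, AFG3L2 8, SPG7 6,
DNM1L 2, MIEF1 2, and 27 across five candidate-gene placeholders;
recessive cases as WFS1 23, ACO2 13, RTN4IP1 9, TMEM126A 5, SPG7 5,
OPA1 3, SLC25A46 1. Variant classes are drawn per gene: OPA1 splice .36 /
nonsense .26 / missense .24 / frameshift .14; all other genes use the
cohort-wide distinct-variant split 120:22:20:28
(missense:nonsense:frameshift:splice). Half of the recessive cases are
compound heterozygous, half homozygous (unstated in the source material;
chosen as the neutral default). Half of the distinct causal variants are
entered in the clinical catalog as reported pathogenic (exercising T1
against the novel tiers); causal variants are absent from the frequency
table, as true ultra-rare alleles would be.

Sites are constructed class-true inside deterministic toy gene models:
one short contig per gene, 2–4 exons with canonical GT..AG introns, a
fully coding CDS seeded with CGA/TGG codons so stop-gains are always
constructible; OPA1 is 300 codons with an approximate domain layout
(GTPase / central dynamin / GED) shipped as configuration, since real
residue ranges must accompany real data. Five genes are placed on the
minus strand to exercise reverse-complement handling. The toy panel is
built from a fixed internal seed and shipped as packaged text files;
a test regenerates it and compares.

Noise channels per caller: dropout (default sensitivity 0.95), caller-
private false-positive SNVs (Poisson, mean 0.5 per caller per proband),
and representation jitter (probability 0.10) that re-expresses indels at
the rightmost equivalent position or buries SNVs in multiallelic records
with an uncarried decoy allele — exactly the discordance normalization
and decomposition must undo. Unsolved probands carry only common benign
background variants (MAF drawn in [0.01, 0.2], above both rarity
thresholds; ~3 per proband). A fraction of solved families (default 0.3)
receives nuclear-family pedigrees whose parental genotypes realize the
truth mode (dominant: one affected carrier parent; recessive: each
parent carries one allele); an injection rate can flip them into
contradictions for negative testing. Depth tracks follow a two-state
Markov chain (low-coverage runs of mean length 20 bp covering ~5 % of
design bases at ≤25×, the rest Poisson around 150×), which makes the
25/50/100× fractions nearly identical by construction. All sampling
flows through one seeded generator; a seed is mandatory and identical
seeds give byte-identical outputs.

What the generator does **not** emulate: read-level errors and mapping
artifacts, systematic (shared) caller errors, population structure in
the frequency tables, CNVs/structural variants, real transcript
complexity (UTRs, long genes, alternative splicing), and mtDNA beyond
the three-mutation LHON screen. Passing tests therefore demonstrate the
correctness of the pipeline's logic under its stated model of caller
discordance, not the sensitivity of any wet-lab assay.

## Statistical checks and problem sizes

The test suite verifies truth recovery of 100 % on noise-free and
jitter-only cohorts of 1,000 probands; consensus detection under 20 %
caller dropout at `min_support` 2 against the analytic tail
P(Bin(6, 0.8) ≥ 2) within three Monte-Carlo standard errors at ~10,000
variants; and, on a 5,000-proband cohort, per-gene solved shares and the
OPA1 class split inside exact (Clopper–Pearson) binomial confidence
intervals of the generator's composition. Because ~24 share checks run
simultaneously, the intervals use a Bonferroni-adjusted level so the
familywise coverage is 95 % — with per-comparison 95 % intervals, at
least one false alarm would be more likely than not. The OPA1 class
split is measured over per-case causal draws rather than deduplicated
keys: the toy OPA1 gene offers only a few dozen distinct splice-site
variants, so recurrent draws collapse under deduplication and the
deduplicated split is not binomial in the class weights. These sizes
keep the full suite under a minute of simulation time while leaving
every standard error small against the tested tolerances.

`scripts/acceptance.py` reports the reconstruction statistics exactly as
the summarizer computes them from the published count tables (rounding
integer-printed values to integers, shares to two decimals) and the
simulation statistics from seeded cohorts: yield at n = 1,102, the OPA1
class split from a dedicated 2,000-case OPA1-dominant cohort, coverage
fractions, recovery rates, and the dropout detection rate with its
analytic expectation.
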