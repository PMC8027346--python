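# ionprior

Molecular-diagnosis pipeline for a 22-gene inherited optic neuropathy (ION)
panel: multi-caller consensus variant calling over normalized alleles,
tiered causative-variant prioritization with pedigree segregation, and
cohort-level diagnostic-yield summarization — together with a synthetic
cohort generator so every stage is testable end to end without patient
data.

## Who this is for

Inherited optic neuropathies (dominant optic atrophy, recessive optic
atrophy, and mtDNA-caused LHON) result from degeneration of retinal
ganglion cells. Clinical laboratories diagnose the autosomal forms by
targeted amplicon sequencing of a gene panel — here 15 known genes (OPA1,
OPA3, WFS1, MFN2, SPG7, AFG3L2, DNM1L, SSBP1, MIEF1, TMEM126A, ACO2,
RTN4IP1, NDUFS2, MCAT, SLC25A46) plus placeholder slots for candidate
genes — followed by variant filtering, classification, and family
segregation. This package implements that computation as a reusable,
tested library for people building or validating such pipelines.

## The method

Per proband, the cascade is:

1. **LHON pre-screen.** Probands carrying one of the three primary mtDNA
   mutations (m.3460G>A, m.11778G>A, m.14484T>C) are excluded before
   autosomal analysis.
2. **Normalization.** Every call from every caller is decomposed to
   biallelic records and rewritten into the canonical parsimonious,
   left-aligned representation, so that `(chrom, pos, ref, alt)` is a
   well-defined variant identity across callers.
3. **Consensus.** A site is retained when called by at least *m* of the
   six callers that ran (TorrentSuite VariantCaller, GATK
   UnifiedGenotyper, VarScan2, SNVer, LoFreq, Platypus); default *m* = 2.
   Genotypes are reconciled by majority vote with a fixed caller-priority
   tie-break.
4. **Annotation.** Gene assignment by panel-region overlap; consequence
   by a transcript-model engine (codon translation for SNVs, length mod 3
   for coding indels, ±2 bp canonical splice windows); population MAF and
   clinical significance from lookup tables keyed on the normalized
   identity.
5. **Prioritization.** Rarity filters with strict inequalities — dominant
   candidates need MAF < 1e-4, recessive < 5e-3 (absent from databases
   always passes) — then a tier ladder: T1 reported pathogenic in a known
   gene, T2 novel loss-of-function (stop-gain / frameshift / splice), T3
   novel missense, T4 qualifying variant in a candidate gene (reported as
   a VUS). Dominant explanations need one heterozygous qualifying
   variant; recessive ones a homozygous variant or two distinct
   heterozygotes (presumed compound het). Where relatives are genotyped,
   segregation-consistent explanations outrank untested ones, which
   outrank inconsistent ones.
6. **Summarization.** Per-gene solved counts and percentage shares by
   mode, overall diagnostic yield, the distinct-variant class tally, and
   the OPA1 exon/domain spectrum.

## Worked example

Run the whole pipeline on a simulated 200-proband cohort:

```bash
cat > run.yaml <<EOF
outdir: demo_run
seed: 11
n_probands: 200
EOF
ionprior run-all --config run.yaml
```

which prints `8 stages completed -> demo_run` and writes
`demo_run/summary.json` containing (for this seed):

```
n_total: 200    n_solved: 41    n_dominant: 30    n_recessive: 11
yield_pct: 20.5
truth_recovery: 1.0
coverage >25x/50x/100x: 0.943 / 0.943 / 0.943
```

Read: 41 of 200 simulated probands received a molecular diagnosis
(20.5 % yield; the generator's default composition targets ~22 %), split
30 dominant / 11 recessive; the pipeline recovered the simulated causal
gene, mode and variants for every solved case despite caller dropout,
representation jitter and caller-private false positives; and ~94 % of
panel design bases were covered above every QC threshold. Per-gene shares
at this n fluctuate binomially (OPA1 took 60 % of dominant cases here
against a 40.9 % target); at n = 5,000 every share lands inside exact
binomial confidence intervals of the target composition — that check is
part of the test suite.

Individual stages are also exposed (`ionprior simulate / normalize /
consensus / annotate / qc / validate`), reading and writing ordinary VCF,
PED, BED, FASTA and TSV files.

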