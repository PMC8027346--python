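"""Synthetic ION cohort generator.

Clinical cohorts behind published diagnostic-yield studies are not
deposited, so this module builds one with the same statistical skeleton:
probands whose causal variants are drawn gene-by-gene from the published
per-mode solved counts (dominant: OPA1 76, ACO2 31, WFS1 23, MFN2 11,
AFG3L2 8, SPG7 6, DNM1L 2, MIEF1 2, candidate genes 27; recessive: WFS1
23, ACO2 13, RTN4IP1 9, TMEM126A 5, SPG7 5, OPA1 3, SLC25A46 1), with
variant classes drawn from the published class spectrum (OPA1: splice .36,
nonsense .26, missense .24, frameshift .14; other genes: the cohort-wide
120/22/20/28 missense/nonsense/frameshift/splice split).

Each of the six emulated callers sees the truth through a noise channel:
per-call dropout (1 − sensitivity), per-caller false-positive calls, and
representation jitter that right-shifts indels inside repeat context or
buries SNVs in multiallelic records — exactly the discordance the
normalize + consensus stages exist to undo.  All randomness flows through
one seeded generator; the same seed reproduces the cohort byte for byte.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import formats_io
from .consensus import CALLER_PRIORITY
from .coverage_qc import design_positions
from .normalize import equivalent_representations, left_align_trim
from .toypanel import OPA1_TOY_DOMAINS, build_toy_panel
from .types import (
    DNA,
    ClinicalTable,
    FrequencyTable,
    Genotype,
    Individual,
    PanelGene,
    Pedigree,
    TranscriptModel,
    VariantKey,
    VariantRecord,
    revcomp,
)

#: Published per-gene solved-proband counts by inheritance mode; the 27
#: dominant candidate-gene families are spread over five placeholder genes.
DOMINANT_GENE_COUNTS: dict[str, int] = {
    "OPA1": 76, "ACO2": 31, "WFS1": 23, "MFN2": 11, "AFG3L2": 8,
    "SPG7": 6, "DNM1L": 2, "MIEF1": 2,
    "CAND1": 6, "CAND2": 6, "CAND3": 5, "CAND4": 5, "CAND5": 5,
}
RECESSIVE_GENE_COUNTS: dict[str, int] = {
    "WFS1": 23, "ACO2": 13, "RTN4IP1": 9, "TMEM126A": 5, "SPG7": 5,
    "OPA1": 3, "SLC25A46": 1,
}

OPA1_CLASS_WEIGHTS = {"splice": 0.36, "nonsense": 0.26, "missense": 0.24, "frameshift": 0.14}
#: Cohort-wide distinct-variant class tally (120/22/20/28 of 190).
DEFAULT_CLASS_WEIGHTS = {
    "missense": 120 / 190, "nonsense": 22 / 190, "frameshift": 20 / 190, "splice": 28 / 190,
}

N_COHORT = 1102
N_SOLVED_DOMINANT = 186
N_SOLVED_RECESSIVE = 59


@dataclass
class CohortSpec:
    """All knobs of the generator; defaults emulate the published cohort."""

    n_probands: int = N_COHORT
    seed: int = 0
    solved_fraction: float = (N_SOLVED_DOMINANT + N_SOLVED_RECESSIVE) / N_COHORT
    dominant_fraction: float = N_SOLVED_DOMINANT / (N_SOLVED_DOMINANT + N_SOLVED_RECESSIVE)
    dominant_gene_weights: dict[str, int] = field(
        default_factory=lambda: dict(DOMINANT_GENE_COUNTS)
    )
    recessive_gene_weights: dict[str, int] = field(
        default_factory=lambda: dict(RECESSIVE_GENE_COUNTS)
    )
    class_weights_by_gene: dict[str, dict[str, float]] = field(
        default_factory=lambda: {"OPA1": dict(OPA1_CLASS_WEIGHTS)}
    )
    default_class_weights: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_WEIGHTS)
    )
    #: fraction of distinct causal variants entered in the clinical catalog
    reported_fraction: float = 0.5
    caller_sensitivity: float = 0.95
    jitter_prob: float = 0.10
    fp_rate: float = 0.5  # expected false calls per caller per proband
    background_rate: float = 3.0  # common benign variants per proband
    pedigree_fraction: float = 0.3
    seg_inconsistency_rate: float = 0.0
    lhon_fraction: float = 0.0
    comphet_fraction: float = 0.5  # of recessive cases (rest homozygous)
    low_coverage_fraction: float = 0.05
    mean_depth: float = 150.0

    def __post_init__(self) -> None:
        for name in (
            "solved_fraction", "dominant_fraction", "reported_fraction",
            "caller_sensitivity", "jitter_prob", "pedigree_fraction",
            "seg_inconsistency_rate", "lhon_fraction", "comphet_fraction",
            "low_coverage_fraction",
        ):
            val = getattr(self, name)
            if not 0.0 <= val <= 1.0:
                raise ValueError(f"{name}={val} outside [0,1]")
        if self.seed is None:
            raise ValueError("seed is mandatory")


@dataclass
class TruthRecord:
    proband_id: str
    family_id: str
    gene: str
    mode: str
    zygosity: str  # het / hom / comphet
    variants: tuple[VariantKey, ...]
    has_pedigree: bool = False


@dataclass
class SyntheticCohort:
    spec: CohortSpec
    panel: list[PanelGene]
    transcripts: dict[str, TranscriptModel]
    reference: dict[str, str]
    truth: list[TruthRecord]
    proband_ids: list[str]
    family_of: dict[str, str]
    calls: dict[str, dict[str, list[VariantRecord]]]  # family -> caller -> records
    pedigrees: dict[str, Pedigree]
    freq_table: FrequencyTable
    clinical_table: ClinicalTable
    depth_track: dict[tuple[str, int], int]
    mt_variants: dict[str, list[tuple[int, str, str]]]

    def write(self, outdir: str | Path) -> None:
        """Write every artifact as plain-text standard formats."""
        out = Path(outdir)
        (out / "vcf").mkdir(parents=True, exist_ok=True)
        formats_io.write_fasta(out / "toy_reference.fa", self.reference)
        formats_io.write_panel(out / "panel_genes.tsv", self.panel)
        formats_io.write_transcripts(out / "transcripts.tsv", self.transcripts)
        formats_io.write_freq_table(out / "freq_table.tsv", self.freq_table)
        formats_io.write_clinical_table(out / "clinical_table.tsv", self.clinical_table)
        formats_io.write_domain_table(out / "opa1_domains.tsv", OPA1_TOY_DOMAINS)
        formats_io.write_ped(out / "cohort.ped", list(self.pedigrees.values()))
        formats_io.write_depth_tsv(out / "depth.tsv", self.depth_track)
        contig_lengths = {c: len(s) for c, s in self.reference.items()}
        for fam, by_caller in self.calls.items():
            samples = sorted(
                {s for recs in by_caller.values() for r in recs for s in r.genotypes}
            )
            for caller, records in by_caller.items():
                formats_io.write_vcf(
                    out / "vcf" / f"{fam}.{caller}.vcf",
                    sorted(records, key=lambda r: (r.chrom, r.pos, r.ref, r.alts)),
                    samples or [self._proband_of(fam)],
                    contig_lengths,
                )
        with open(out / "truth.tsv", "w") as fh:
            fh.write("proband\tfamily\tgene\tmode\tzygosity\tvariants\thas_pedigree\n")
            for t in self.truth:
                vstr = ";".join(f"{k.chrom}:{k.pos}:{k.ref}:{k.alt}" for k in t.variants)
                fh.write(
                    f"{t.proband_id}\t{t.family_id}\t{t.gene}\t{t.mode}\t"
                    f"{t.zygosity}\t{vstr}\t{int(t.has_pedigree)}\n"
                )
        if any(self.mt_variants.values()):
            with open(out / "mt_variants.tsv", "w") as fh:
                fh.write("proband\tpos\tref\talt\n")
                for pid, muts in self.mt_variants.items():
                    for pos, ref, alt in muts:
                        fh.write(f"{pid}\t{pos}\t{ref}\t{alt}\n")

    def _proband_of(self, fam: str) -> str:
        for pid, f in self.family_of.items():
            if f == fam:
                return pid
        raise KeyError(fam)


# ---------------------------------------------------------------------------
# causal-site construction
# ---------------------------------------------------------------------------

class _SiteFactory:
    """Draws class-true causal variants inside one toy gene."""

    def __init__(self, tx: TranscriptModel, reference: dict[str, str], rng):
        self.tx = tx
        self.seq = reference[tx.chrom]
        self.rng = rng
        self.cds = tx.spliced_cds(reference)
        self._nonsense_sites: list[tuple[int, str]] | None = None

    def _cds_to_genomic(self, cds_idx: int) -> int:
        """0-based genomic position of CDS index (transcription orientation)."""
        j = cds_idx if self.tx.strand == "+" else self.tx.cds_len - 1 - cds_idx
        offset = 0
        for s, e in self.tx.cds_exons:
            if j < offset + (e - s):
                return s + (j - offset)
            offset += e - s
        raise IndexError(cds_idx)

    def _genomic_alt(self, base_tx: str) -> str:
        return base_tx if self.tx.strand == "+" else revcomp(base_tx)

    def snv(self, kind: str) -> VariantKey:
        """Random missense or nonsense SNV (kind in {'missense','nonsense'})."""
        if kind == "nonsense":
            if self._nonsense_sites is None:
                sites = []
                for i in range(0, self.tx.cds_len - 3, 3):  # skip terminal stop
                    codon = self.cds[i : i + 3]
                    for w in range(3):
                        for b in DNA:
                            if b == codon[w]:
                                continue
                            if codon[:w] + b + codon[w + 1 :] in ("TAA", "TAG", "TGA"):
                                sites.append((i + w, b))
                self._nonsense_sites = sites
            idx, alt_tx = self._nonsense_sites[self.rng.integers(len(self._nonsense_sites))]
            pos0 = self._cds_to_genomic(idx)
            return VariantKey(
                self.tx.chrom, pos0 + 1, self.seq[pos0], self._genomic_alt(alt_tx)
            )
        # missense: rejection-sample a codon-changing, non-stop SNV
        from Bio.Seq import Seq

        while True:
            idx = int(self.rng.integers(3, self.tx.cds_len - 3))  # keep start + stop
            codon_i, w = divmod(idx, 3)
            codon = self.cds[codon_i * 3 : codon_i * 3 + 3]
            alt_tx = DNA[self.rng.integers(4)]
            if alt_tx == codon[w]:
                continue
            new = codon[:w] + alt_tx + codon[w + 1 :]
            if new in ("TAA", "TAG", "TGA"):
                continue
            if str(Seq(new).translate()) == str(Seq(codon).translate()):
                continue
            pos0 = self._cds_to_genomic(idx)
            return VariantKey(
                self.tx.chrom, pos0 + 1, self.seq[pos0], self._genomic_alt(alt_tx)
            )

    def frameshift(self) -> VariantKey:
        """1–2 bp indel fully inside a coding exon, normalized."""
        while True:
            cs, ce = self.tx.cds_exons[self.rng.integers(len(self.tx.cds_exons))]
            if ce - cs < 12:
                continue
            length = int(self.rng.integers(1, 3))
            anchor0 = int(self.rng.integers(cs + 2, ce - length - 2))
            if self.rng.random() < 0.5:  # deletion
                ref = self.seq[anchor0 : anchor0 + 1 + length]
                alt = ref[0]
            else:  # insertion
                ref = self.seq[anchor0]
                alt = ref + "".join(DNA[self.rng.integers(4)] for _ in range(length))
            pos, nref, nalt = left_align_trim(
                self.tx.chrom, anchor0 + 1, ref, alt, self.seq
            )
            # keep the normalized edit clear of splice windows and exon edges
            lo, hi = pos - 1, pos - 1 + len(nref)
            if cs + 1 <= lo and hi <= ce - 1:
                return VariantKey(self.tx.chrom, pos, nref, nalt)

    def splice(self) -> VariantKey:
        windows = self.tx.splice_windows(2)
        ws, we = windows[self.rng.integers(len(windows))]
        pos0 = int(self.rng.integers(ws, we))
        ref = self.seq[pos0]
        alt = DNA[(DNA.index(ref) + 1 + int(self.rng.integers(3))) % 4]
        return VariantKey(self.tx.chrom, pos0 + 1, ref, alt)

    def draw(self, cls: str) -> VariantKey:
        if cls in ("missense", "nonsense"):
            return self.snv(cls)
        if cls == "frameshift":
            return self.frameshift()
        if cls == "splice":
            return self.splice()
        raise ValueError(f"unsupported causal class {cls!r}")


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

def _weighted_choice(rng, weights: dict[str, float]) -> str:
    items = [k for k, w in weights.items() if w > 0]
    w = np.array([weights[k] for k in items], dtype=float)
    return items[rng.choice(len(items), p=w / w.sum())]


def _jitter_indel(key: VariantKey, reference: dict[str, str], rng) -> VariantKey:
    """Re-express an indel at the rightmost equivalent position, if any."""
    seq = reference[key.chrom]
    pad = 30
    lo = max(0, key.pos - 1 - pad)
    hi = min(len(seq), key.pos - 1 + len(key.ref) + pad)
    window = seq[lo:hi]
    reps = equivalent_representations(window, key.pos - lo, key.ref, key.alt)
    reps = [r for r in reps if (r[0] + lo, r[1], r[2]) != (key.pos, key.ref, key.alt)]
    if not reps:
        return key
    p, r, a = max(reps, key=lambda t: (t[0], len(t[1])))
    return VariantKey(key.chrom, p + lo, r, a)


def _decoy_alt(ref: str, alt: str, rng) -> str:
    for _ in range(10):
        b = DNA[rng.integers(4)]
        if b != ref[0] and b != alt:
            return b
    return "N"


def generate(spec: CohortSpec) -> SyntheticCohort:
    """Build the full synthetic cohort deterministically from spec.seed."""
    rng = np.random.default_rng(spec.seed)
    transcripts, panel_by_gene, reference = build_toy_panel()
    panel = list(panel_by_gene.values())
    factories = {
        g: _SiteFactory(tx, reference, rng) for g, tx in transcripts.items()
    }

    n = spec.n_probands
    proband_ids = [f"P{i:05d}" for i in range(1, n + 1)]
    family_ids = [f"F{i:05d}" for i in range(1, n + 1)]
    family_of = dict(zip(proband_ids, family_ids))

    n_solved = int(round(spec.solved_fraction * n))
    n_dom = int(round(spec.dominant_fraction * n_solved))
    modes = ["dominant"] * n_dom + ["recessive"] * (n_solved - n_dom)

    truth: list[TruthRecord] = []
    causal_keys: set[VariantKey] = set()
    clinical = ClinicalTable()
    reported_decision: dict[VariantKey, bool] = {}
    mt_variants: dict[str, list[tuple[int, str, str]]] = {p: [] for p in proband_ids}

    for i, mode in enumerate(modes):
        pid, fam = proband_ids[i], family_ids[i]
        weights = (
            spec.dominant_gene_weights if mode == "dominant" else spec.recessive_gene_weights
        )
        gene = _weighted_choice(rng, {k: float(v) for k, v in weights.items()})
        cls_weights = spec.class_weights_by_gene.get(gene, spec.default_class_weights)
        if mode == "dominant":
            key = factories[gene].draw(_weighted_choice(rng, cls_weights))
            keys, zyg = (key,), "het"
        else:
            if rng.random() < spec.comphet_fraction:
                k1 = factories[gene].draw(_weighted_choice(rng, cls_weights))
                k2 = k1
                while k2 == k1:
                    k2 = factories[gene].draw(_weighted_choice(rng, cls_weights))
                keys, zyg = tuple(sorted((k1, k2))), "comphet"
            else:
                keys, zyg = (factories[gene].draw(_weighted_choice(rng, cls_weights)),), "hom"
        for key in keys:
            causal_keys.add(key)
            if key not in reported_decision:
                reported = (
                    panel_by_gene[gene].status == "known"
                    and rng.random() < spec.reported_fraction
                )
                reported_decision[key] = reported
                if reported:
                    clinical[key] = "pathogenic"
        truth.append(TruthRecord(pid, fam, gene, mode, zyg, keys))

    # probands excluded by the mtDNA pre-screen carry a primary LHON mutation
    for i in range(n):
        if rng.random() < spec.lhon_fraction:
            mt_variants[proband_ids[i]].append((11778, "G", "A"))

    # pedigrees for a sample of solved families
    pedigrees: dict[str, Pedigree] = {}
    relative_gt: dict[str, dict[VariantKey, Genotype]] = {}
    for t in truth:
        if rng.random() >= spec.pedigree_fraction:
            continue
        t.has_pedigree = True
        inject = rng.random() < spec.seg_inconsistency_rate
        pedigrees[t.family_id], rel_gts = _make_family(t, rng, inject)
        relative_gt.update(rel_gts)

    # background benign variants, with population frequencies above both
    # mode thresholds so they exercise the MAF filter without qualifying
    freq = FrequencyTable()
    genes = list(transcripts)
    background: dict[str, list[VariantKey]] = {p: [] for p in proband_ids}
    n_bg = rng.poisson(spec.background_rate, size=n)
    for i, pid in enumerate(proband_ids):
        for _ in range(int(n_bg[i])):
            key = _random_snv(genes, transcripts, reference, rng)
            if key in causal_keys:
                continue
            background[pid].append(key)
            if key not in freq:
                freq[key] = float(rng.uniform(0.01, 0.2))
                if rng.random() < 0.3:
                    clinical[key] = "benign"

    # per-caller noisy call sets
    calls: dict[str, dict[str, list[VariantRecord]]] = {}
    for i, pid in enumerate(proband_ids):
        fam = family_ids[i]
        t = truth[i] if i < len(truth) else None
        site_gts: dict[VariantKey, dict[str, Genotype]] = {}
        if t is not None:
            for key in t.variants:
                gt = Genotype((1, 1)) if t.zygosity == "hom" else Genotype((0, 1))
                site_gts[key] = {pid: gt}
        for key in background[pid]:
            site_gts.setdefault(key, {})[pid] = Genotype((0, 1))
        # merge relative genotypes for this family
        ped = pedigrees.get(fam)
        if ped is not None:
            for ind in ped.relatives():
                gts = relative_gt.get(ind.iid, {})
                for key, gt in gts.items():
                    site_gts.setdefault(key, {})[ind.iid] = gt
        samples = [pid] + ([ind.iid for ind in ped.relatives()] if ped else [])
        calls[fam] = _emit_caller_calls(
            site_gts, samples, reference, transcripts, genes, spec, rng, causal_keys
        )

    depth_track = _make_depth_track(panel, spec, rng)

    return SyntheticCohort(
        spec=spec,
        panel=panel,
        transcripts=transcripts,
        reference=reference,
        truth=truth,
        proband_ids=proband_ids,
        family_of=family_of,
        calls=calls,
        pedigrees=pedigrees,
        freq_table=freq,
        clinical_table=clinical,
        depth_track=depth_track,
        mt_variants=mt_variants,
    )


def _random_snv(genes, transcripts, reference, rng) -> VariantKey:
    gene = genes[rng.integers(len(genes))]
    tx = transcripts[gene]
    pos0 = int(rng.integers(tx.tx_start0, tx.tx_end0))
    ref = reference[tx.chrom][pos0]
    alt = DNA[(DNA.index(ref) + 1 + int(rng.integers(3))) % 4]
    return VariantKey(tx.chrom, pos0 + 1, ref, alt)


def _make_family(
    truth: TruthRecord, rng, inject_inconsistency: bool
) -> tuple[Pedigree, dict[str, dict[VariantKey, Genotype]]]:
    """Build a nuclear family whose genotypes realize (or, when injecting,
    contradict) the truth inheritance mode."""
    pid, fam = truth.proband_id, truth.family_id
    father, mother = f"{pid}_f", f"{pid}_m"
    rel_gts: dict[str, dict[VariantKey, Genotype]] = {father: {}, mother: {}}
    hom_ref = Genotype((0, 0))
    if truth.mode == "dominant":
        key = truth.variants[0]
        carrier, other = (father, mother) if rng.random() < 0.5 else (mother, father)
        carrier_affected = "yes"
        if inject_inconsistency:
            # affected parent who does NOT carry the variant
            rel_gts[carrier][key] = hom_ref
        else:
            rel_gts[carrier][key] = Genotype((0, 1))
        rel_gts[other][key] = hom_ref
        individuals = [
            Individual(father, None, None, 1, carrier_affected if carrier == father else "no"),
            Individual(mother, None, None, 2, carrier_affected if carrier == mother else "no"),
            Individual(pid, father, mother, int(rng.integers(1, 3)), "yes"),
        ]
    else:
        if truth.zygosity == "comphet":
            k1, k2 = truth.variants
            rel_gts[father][k1] = Genotype((0, 1))
            rel_gts[father][k2] = hom_ref
            rel_gts[mother][k2] = Genotype((0, 1))
            rel_gts[mother][k1] = hom_ref
            if inject_inconsistency:  # both alleles on one parental haplotype
                rel_gts[father][k2] = Genotype((0, 1))
        else:
            key = truth.variants[0]
            rel_gts[father][key] = Genotype((0, 1))
            rel_gts[mother][key] = Genotype((0, 1))
            if inject_inconsistency:  # unaffected parent is biallelic
                rel_gts[father][key] = Genotype((1, 1))
        individuals = [
            Individual(father, None, None, 1, "no"),
            Individual(mother, None, None, 2, "no"),
            Individual(pid, father, mother, int(rng.integers(1, 3)), "yes"),
        ]
    return Pedigree(family_id=fam, individuals=individuals, proband=pid), rel_gts


def _emit_caller_calls(
    site_gts: dict[VariantKey, dict[str, Genotype]],
    samples: list[str],
    reference: dict[str, str],
    transcripts: dict[str, TranscriptModel],
    genes: list[str],
    spec: CohortSpec,
    rng,
    causal_keys: set[VariantKey],
) -> dict[str, list[VariantRecord]]:
    by_caller: dict[str, list[VariantRecord]] = {c: [] for c in CALLER_PRIORITY}
    for key in sorted(site_gts):
        gts = {s: site_gts[key].get(s, Genotype((0, 0))) for s in samples}
        is_indel = len(key.ref) != len(key.alt)
        for caller in CALLER_PRIORITY:
            if rng.random() >= spec.caller_sensitivity:
                continue  # dropout
            ckey, alts = key, (key.alt,)
            cgts = gts
            if rng.random() < spec.jitter_prob:
                if is_indel:
                    ckey = _jitter_indel(key, reference, rng)
                else:  # bury the SNV in a multiallelic record
                    alts = (key.alt, _decoy_alt(key.ref, key.alt, rng))
            by_caller[caller].append(
                VariantRecord(
                    chrom=ckey.chrom,
                    pos=ckey.pos,
                    ref=ckey.ref,
                    alts=(ckey.alt,) if ckey is not key else alts,
                    genotypes=dict(cgts),
                    caller=caller,
                )
            )
    # caller-private false positives
    for caller in CALLER_PRIORITY:
        for _ in range(int(rng.poisson(spec.fp_rate))):
            key = _random_snv(genes, transcripts, reference, rng)
            if key in causal_keys or key in site_gts:
                continue
            gts = {s: Genotype((0, 0)) for s in samples}
            gts[samples[0]] = Genotype((0, 1))
            by_caller[caller].append(
                VariantRecord(
                    chrom=key.chrom, pos=key.pos, ref=key.ref, alts=(key.alt,),
                    genotypes=gts, caller=caller,
                )
            )
    return by_caller


def _make_depth_track(
    panel: list[PanelGene], spec: CohortSpec, rng
) -> dict[tuple[str, int], int]:
    """Two-state Markov depth profile: long well-covered stretches broken by
    occasional low-coverage runs (mean length ~20 bp) so that roughly
    ``low_coverage_fraction`` of design bases sit at or below 25x."""
    positions = design_positions(panel)
    pi_low = spec.low_coverage_fraction
    p_exit_low = 0.05
    p_enter_low = p_exit_low * pi_low / (1.0 - pi_low)
    track: dict[tuple[str, int], int] = {}
    low = rng.random() < pi_low
    prev = None
    for chrom, pos in positions:
        if prev is not None and (chrom != prev[0] or pos != prev[1] + 1):
            low = rng.random() < pi_low  # restart the chain across gaps
        elif low:
            low = rng.random() >= p_exit_low
        else:
            low = rng.random() < p_enter_low
        depth = int(rng.integers(0, 26)) if low else int(rng.poisson(spec.mean_depth))
        track[(chrom, pos)] = depth
        prev = (chrom, pos)
    return track
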