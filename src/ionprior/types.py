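"""Shared domain types for the ION panel diagnostic pipeline.

Conventions used throughout the package:

* Genomic positions are 1-based inclusive at module boundaries (VCF
  convention) and 0-based half-open internally.  All conversions live in
  :mod:`ionprior.formats_io`.
* A variant "key" is the tuple ``(chrom, pos, ref, alt)`` of a normalized,
  biallelic representation; two calls are the same variant iff their keys
  are equal after normalization.
* Inheritance modes are the strings ``"dominant"`` and ``"recessive"``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

MODES = ("dominant", "recessive")

CONSEQUENCES = (
    "missense",
    "nonsense",
    "synonymous",
    "frameshift",
    "inframe_indel",
    "splice",
    "intronic",
    "intergenic",
)

#: Consequence classes counted as loss-of-function (stop-gain, frameshift,
#: splice-disrupting).
LOF_CONSEQUENCES = frozenset({"nonsense", "frameshift", "splice"})

CLINICAL_LEVELS = ("pathogenic", "likely_pathogenic", "benign", "vus")

TIERS = (
    "T1_reported_pathogenic",
    "T2_novel_lof",
    "T3_novel_missense",
    "T4_candidate_vus",
)

STATUSES = (
    "solved_dominant",
    "solved_recessive",
    "vus_candidate",
    "unsolved",
    "excluded_lhon",
)

DNA = "ACGT"

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class VariantKey(NamedTuple):
    """Identity of a normalized biallelic variant."""

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str


class Genotype(NamedTuple):
    """Diploid genotype as a pair of allele indices (0=ref, k=k-th alt, -1=missing)."""

    allele_indices: tuple[int, int]
    phased: bool = False

    @classmethod
    def missing(cls) -> "Genotype":
        return cls((-1, -1))

    @property
    def is_missing(self) -> bool:
        return all(a < 0 for a in self.allele_indices)

    def alt_count(self, alt_index: int = 1) -> int:
        return sum(1 for a in self.allele_indices if a == alt_index)

    def carries(self, alt_index: int = 1) -> bool:
        return self.alt_count(alt_index) > 0

    @property
    def is_het(self) -> bool:
        a, b = self.allele_indices
        return a >= 0 and b >= 0 and a != b

    def is_hom_alt(self, alt_index: int = 1) -> bool:
        return self.allele_indices == (alt_index, alt_index)

    def vcf_string(self) -> str:
        sep = "|" if self.phased else "/"
        return sep.join("." if a < 0 else str(a) for a in self.allele_indices)


@dataclass
class VariantRecord:
    """One VCF data line from one caller: a locus with one or more alt alleles."""

    chrom: str
    pos: int  # 1-based position of the first ref base
    ref: str
    alts: tuple[str, ...]
    genotypes: dict[str, Genotype]
    caller: str
    quality_pass: bool = True

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if not self.ref or not self.ref.isupper():
            raise ValueError(f"ref allele must be nonempty uppercase: {self.ref!r}")
        self.alts = tuple(self.alts)
        if not self.alts:
            raise ValueError("alts must be a nonempty list")
        for alt in self.alts:
            if not alt or not alt.isupper():
                raise ValueError(f"alt allele must be nonempty uppercase: {alt!r}")
            if alt == self.ref:
                raise ValueError(f"ref == alt ({alt}) at {self.chrom}:{self.pos}")
        n_alleles = len(self.alts) + 1
        for sample, gt in self.genotypes.items():
            for a in gt.allele_indices:
                if a >= n_alleles:
                    raise ValueError(
                        f"genotype index {a} out of range for sample {sample} "
                        f"at {self.chrom}:{self.pos} ({n_alleles} alleles)"
                    )


@dataclass
class NormalizedVariant:
    """A biallelic variant in canonical (parsimonious, left-aligned) form.

    ``provenance`` records every (caller, original chrom:pos:ref:alt) that
    normalized to this representation; ``genotypes`` are per-sample with
    allele indices restricted to {−1, 0, 1}.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    genotypes: dict[str, Genotype] = field(default_factory=dict)
    provenance: frozenset = frozenset()
    quality_pass: bool = True

    @property
    def key(self) -> VariantKey:
        return VariantKey(self.chrom, self.pos, self.ref, self.alt)

    @property
    def is_snv(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1

    @property
    def is_indel(self) -> bool:
        return len(self.ref) != len(self.alt)


@dataclass
class PanelGene:
    """One gene of the diagnostic panel with its design regions.

    ``regions`` are (chrom, start0, end0) half-open intervals, sorted and
    non-overlapping; ``modes`` is the set of inheritance modes under which
    the gene is interpreted; ``status`` is ``known`` or ``candidate``.
    """

    symbol: str
    modes: frozenset[str]
    status: str
    regions: list[tuple[str, int, int]]

    def __post_init__(self) -> None:
        if not self.modes:
            raise ValueError(f"{self.symbol}: modes must be nonempty")
        bad = set(self.modes) - set(MODES)
        if bad:
            raise ValueError(f"{self.symbol}: unknown inheritance mode(s) {sorted(bad)}")
        if self.status not in ("known", "candidate"):
            raise ValueError(f"{self.symbol}: unknown status {self.status!r}")
        self.regions = sorted(self.regions)
        for (c1, s1, e1), (c2, s2, e2) in zip(self.regions, self.regions[1:]):
            if c1 == c2 and e1 > s2:
                raise ValueError(f"{self.symbol}: overlapping regions after sorting")

    def overlaps(self, chrom: str, start0: int, end0: int) -> bool:
        return any(c == chrom and s < end0 and start0 < e for c, s, e in self.regions)


class Individual(NamedTuple):
    iid: str
    father: str | None
    mother: str | None
    sex: int  # 1 male, 2 female, 0 unknown
    affected: str  # yes / no / unknown


@dataclass
class Pedigree:
    family_id: str
    individuals: list[Individual]
    proband: str | None = None

    def __post_init__(self) -> None:
        ids = {ind.iid for ind in self.individuals}
        if len(ids) != len(self.individuals):
            raise ValueError(f"family {self.family_id}: duplicate individual ids")
        for ind in self.individuals:
            for parent in (ind.father, ind.mother):
                if parent is not None and parent not in ids:
                    raise ValueError(
                        f"family {self.family_id}: dangling parent id {parent!r}"
                    )
        if self.proband is not None and self.proband not in ids:
            raise ValueError(f"family {self.family_id}: proband {self.proband!r} unknown")

    def get(self, iid: str) -> Individual:
        for ind in self.individuals:
            if ind.iid == iid:
                return ind
        raise KeyError(iid)

    def relatives(self) -> list[Individual]:
        """All individuals except the proband."""
        return [i for i in self.individuals if i.iid != self.proband]


class FrequencyTable(dict):
    """Map VariantKey → population minor-allele frequency in [0, 1].

    A key absent from the table means the variant is absent from the public
    databases backing it (which the prioritizer treats as MAF 0).
    """

    def __setitem__(self, key, value):
        if not 0.0 <= value <= 1.0:
            raise ValueError(f"MAF {value} outside [0,1] for {key}")
        super().__setitem__(VariantKey(*key), float(value))

    def maf(self, key: VariantKey) -> float | None:
        return self.get(VariantKey(*key))


class ClinicalTable(dict):
    """Map VariantKey → clinical significance. Absent keys are unreported."""

    def __setitem__(self, key, value):
        if value not in CLINICAL_LEVELS:
            raise ValueError(f"unknown clinical significance {value!r}")
        super().__setitem__(VariantKey(*key), value)

    def significance(self, key: VariantKey) -> str | None:
        return self.get(VariantKey(*key))


@dataclass
class TranscriptModel:
    """Minimal transcript: ordered exons plus a fully coding CDS span.

    Exons are (start0, end0) genomic half-open intervals in ascending
    genomic order; ``strand`` is ``+`` or ``-``; exon numbering follows
    transcription order (reversed for minus-strand genes).  The CDS is the
    [cds_start0, cds_end0) genomic span intersected with the exons; its
    spliced length must be divisible by 3.
    """

    gene: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]
    cds_start0: int
    cds_end0: int

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"{self.gene}: bad strand {self.strand!r}")
        self.exons = sorted(self.exons)
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            if e1 >= s2:
                raise ValueError(f"{self.gene}: exons overlap or touch")
        if not (self.exons[0][0] <= self.cds_start0 < self.cds_end0 <= self.exons[-1][1]):
            raise ValueError(f"{self.gene}: CDS outside exon span")
        if self.cds_len % 3 != 0:
            raise ValueError(f"{self.gene}: CDS length {self.cds_len} not divisible by 3")

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    @property
    def tx_start0(self) -> int:
        return self.exons[0][0]

    @property
    def tx_end0(self) -> int:
        return self.exons[-1][1]

    @property
    def cds_exons(self) -> list[tuple[int, int]]:
        out = []
        for s, e in self.exons:
            s2, e2 = max(s, self.cds_start0), min(e, self.cds_end0)
            if s2 < e2:
                out.append((s2, e2))
        return out

    @property
    def cds_len(self) -> int:
        return sum(e - s for s, e in self.cds_exons)

    def exon_number_at(self, pos0: int) -> int | None:
        """1-based exon number in transcription order, or None if intronic."""
        for i, (s, e) in enumerate(self.exons):
            if s <= pos0 < e:
                return i + 1 if self.strand == "+" else self.n_exons - i
        return None

    def splice_windows(self, window: int = 2) -> list[tuple[int, int]]:
        """Intronic (start0, end0) windows flanking each exon-intron junction."""
        out = []
        for i, (s, e) in enumerate(self.exons):
            if i > 0:  # acceptor side: intron bases immediately 5' of exon start
                out.append((s - window, s))
            if i < self.n_exons - 1:  # donor side: intron bases just 3' of exon end
                out.append((e, e + window))
        return out

    def genomic_to_cds(self, pos0: int) -> int | None:
        """0-based CDS coordinate (transcription orientation) or None."""
        offset = 0
        for s, e in self.cds_exons:
            if s <= pos0 < e:
                cds_plus = offset + (pos0 - s)
                if self.strand == "+":
                    return cds_plus
                return self.cds_len - 1 - cds_plus
            offset += e - s
        return None

    def spliced_cds(self, reference: dict[str, str]) -> str:
        seq = "".join(reference[self.chrom][s:e] for s, e in self.cds_exons)
        return seq if self.strand == "+" else revcomp(seq)


@dataclass
class AnnotatedVariant:
    """A normalized variant with gene, consequence, MAF and clinical context."""

    variant: NormalizedVariant
    gene: str | None
    consequence: str
    maf: float | None = None
    clinical: str | None = None
    exon_number: int | None = None
    protein_change: str | None = None
    ambiguous_genes: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.consequence not in CONSEQUENCES:
            raise ValueError(f"unknown consequence {self.consequence!r}")

    @property
    def key(self) -> VariantKey:
        return self.variant.key

    @property
    def is_lof(self) -> bool:
        return self.consequence in LOF_CONSEQUENCES

    @property
    def maf_or_zero(self) -> float:
        return 0.0 if self.maf is None else self.maf

    def genotype(self, sample: str) -> Genotype:
        return self.variant.genotypes.get(sample, Genotype.missing())


@dataclass
class ConsensusVariant:
    """A variant retained by the multi-caller consensus for one family/sample."""

    key: VariantKey
    sample_id: str
    support: frozenset[str]
    genotypes: dict[str, Genotype]
    n_callers_run: int
    quality_pass: bool = True
    provenance: frozenset = frozenset()

    def __post_init__(self) -> None:
        if not self.support:
            raise ValueError("consensus variant must have nonempty caller support")
        if len(self.support) > self.n_callers_run:
            raise ValueError("support exceeds number of callers run")


@dataclass
class MafThresholds:
    """Mode-specific rarity cut-offs; a variant passes with MAF strictly below."""

    dominant_max: float = 0.0001
    recessive_max: float = 0.005

    def __post_init__(self) -> None:
        if not (0.0 < self.dominant_max <= self.recessive_max < 1.0):
            raise ValueError(
                f"need 0 < dominant_max <= recessive_max < 1, got "
                f"{self.dominant_max}, {self.recessive_max}"
            )

    def for_mode(self, mode: str) -> float:
        if mode == "dominant":
            return self.dominant_max
        if mode == "recessive":
            return self.recessive_max
        raise ValueError(f"unknown mode {mode!r}")


@dataclass
class CaseClassification:
    """Diagnostic outcome for one proband."""

    proband_id: str
    status: str
    gene: str | None = None
    mode: str | None = None
    tier: str | None = None
    causal_variants: tuple[VariantKey, ...] = ()
    segregation: str = "untested"
    flags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.status not in STATUSES:
            raise ValueError(f"unknown status {self.status!r}")
        if self.tier is not None and self.tier not in TIERS:
            raise ValueError(f"unknown tier {self.tier!r}")
        if self.segregation not in ("consistent", "inconsistent", "untested"):
            raise ValueError(f"unknown segregation {self.segregation!r}")

    @property
    def solved(self) -> bool:
        return self.status in ("solved_dominant", "solved_recessive")
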