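"""Causative-variant prioritization: the per-proband diagnostic cascade.

The cascade mirrors clinical ION panel practice:

1. **LHON pre-screen** — probands carrying one of the three primary
   mitochondrial LHON mutations (m.3460G>A, m.11778G>A, m.14484T>C) are
   excluded before autosomal analysis.
2. **Rarity filter** — candidate variants must be absent from population
   databases or rarer than a mode-specific MAF cut-off (dominant < 1e-4,
   recessive < 5e-3, strict inequality).
3. **Tier ladder** — reported pathogenic variants in known genes (T1),
   then novel loss-of-function (T2), then novel missense (T3) in known
   genes, then qualifying variants in candidate genes (T4, reported as
   variants of uncertain significance).
4. **Genotype pattern** — dominant explanations need a single heterozygous
   variant in a dominant-capable gene; recessive ones a homozygous variant
   or two distinct heterozygotes (presumed compound het; phase is unknown
   unless a genotyped parent carries both, which refutes trans
   configuration) in a recessive-capable gene.
5. **Segregation** — where relatives are genotyped, explanations
   consistent with the pedigree outrank untested ones, which outrank
   inconsistent ones.
"""

from __future__ import annotations

from dataclasses import dataclass

from .types import (
    AnnotatedVariant,
    CaseClassification,
    Genotype,
    MafThresholds,
    PanelGene,
    Pedigree,
    TIERS,
)

#: The three primary LHON mtDNA mutations as (position, ref, alt).
PRIMARY_LHON_MUTATIONS = frozenset(
    {(3460, "G", "A"), (11778, "G", "A"), (14484, "T", "C")}
)

_SEG_RANK = {"consistent": 0, "untested": 1, "inconsistent": 2}
_TIER_RANK = {t: i for i, t in enumerate(TIERS)}


def lhon_screen(mt_variants: list[tuple[int, str, str]]) -> str:
    """'excluded' iff any primary LHON mutation is present (exact allele match)."""
    present = {(int(p), r, a) for p, r, a in mt_variants}
    return "excluded" if present & PRIMARY_LHON_MUTATIONS else "retained"


def maf_filter(v: AnnotatedVariant, mode: str, thresholds: MafThresholds) -> bool:
    """Pass iff the variant is absent from frequency tables or strictly
    rarer than the mode's threshold."""
    if v.maf is None:
        return True
    return v.maf < thresholds.for_mode(mode)


def assign_tier(v: AnnotatedVariant, gene: PanelGene) -> str | None:
    """Tier of one qualifying variant in its gene context, or None.

    'Novel' means unreported in the clinical table; benign and
    vus-catalogued variants never qualify for the novel tiers.
    """
    if v.clinical == "benign":
        return None
    if gene.status == "known":
        if v.clinical in ("pathogenic", "likely_pathogenic"):
            return "T1_reported_pathogenic"
        if v.clinical is None:
            if v.is_lof:
                return "T2_novel_lof"
            if v.consequence == "missense":
                return "T3_novel_missense"
        return None
    # candidate-status gene: any qualifying (LoF or missense) variant is a VUS
    if v.is_lof or v.consequence == "missense" or v.clinical in (
        "pathogenic",
        "likely_pathogenic",
    ):
        return "T4_candidate_vus"
    return None


def detect_genotype_pattern(
    variants: list[AnnotatedVariant], proband: str
) -> str:
    """'biallelic' iff one homozygous variant or >=2 distinct het variants."""
    hom = [v for v in variants if v.genotype(proband).is_hom_alt(1)]
    het = [v for v in variants if v.genotype(proband).is_het]
    if hom or len({v.key for v in het}) >= 2:
        return "biallelic"
    return "monoallelic_het"


def _genotyped_relatives(
    variants: list[AnnotatedVariant], pedigree: Pedigree
) -> list:
    rels = []
    for ind in pedigree.relatives():
        gts = [v.genotype(ind.iid) for v in variants]
        if any(not g.is_missing for g in gts):
            rels.append((ind, gts))
    return rels


def check_segregation(
    variants: list[AnnotatedVariant],
    pedigree: Pedigree | None,
    mode: str,
    allow_unaffected_carriers: bool = False,
) -> str:
    """Test whether the candidate explanation co-segregates with disease.

    Dominant: every genotyped affected relative must carry the variant;
    under strict mode (default) no genotyped unaffected relative may carry
    it.  Recessive: every genotyped affected relative must be biallelic and
    no genotyped unaffected relative may be; additionally a genotyped
    parent carrying both alleles of a presumed compound het refutes the
    trans configuration.  'untested' when no non-proband relative is
    genotyped.
    """
    if pedigree is None:
        return "untested"
    rels = _genotyped_relatives(variants, pedigree)
    if not rels:
        return "untested"

    def biallelic(gts: list[Genotype]) -> bool:
        if any(g.is_hom_alt(1) for g in gts):
            return True
        return sum(1 for g in gts if g.carries(1)) >= 2

    if mode == "dominant":
        gts0 = [gts[0] for _, gts in rels]  # single causal variant
        for (ind, _), gt in zip(rels, gts0):
            if ind.affected == "yes" and not gt.carries(1):
                return "inconsistent"
            if (
                ind.affected == "no"
                and gt.carries(1)
                and not allow_unaffected_carriers
            ):
                return "inconsistent"
        return "consistent"

    # recessive
    for ind, gts in rels:
        if ind.affected == "yes" and not biallelic(gts):
            return "inconsistent"
        if ind.affected == "no" and biallelic(gts):
            return "inconsistent"
        # cis refutation: a parent of the proband carrying both hets
        if len(variants) >= 2 and ind.iid in _parents_of(pedigree):
            if all(g.carries(1) for g in gts):
                return "inconsistent"
    return "consistent"


def _parents_of(pedigree: Pedigree) -> set[str]:
    if pedigree.proband is None:
        return set()
    pro = pedigree.get(pedigree.proband)
    return {p for p in (pro.father, pro.mother) if p is not None}


@dataclass
class _Candidate:
    gene: PanelGene
    mode: str
    tier: str
    variants: tuple[AnnotatedVariant, ...]
    segregation: str
    flags: tuple[str, ...] = ()

    @property
    def sort_key(self):
        return (
            _TIER_RANK[self.tier],
            _SEG_RANK[self.segregation],
            0 if self.mode == "recessive" else 1,  # biallelic beats monoallelic
            self.gene.symbol,
        )


def _dominant_candidates(
    gene: PanelGene,
    variants: list[AnnotatedVariant],
    proband: str,
    pedigree: Pedigree | None,
    thresholds: MafThresholds,
    allow_unaffected_carriers: bool,
) -> list[_Candidate]:
    out = []
    for v in variants:
        if not v.genotype(proband).is_het:
            continue
        if not maf_filter(v, "dominant", thresholds):
            continue
        tier = assign_tier(v, gene)
        if tier is None:
            continue
        seg = check_segregation([v], pedigree, "dominant", allow_unaffected_carriers)
        out.append(_Candidate(gene, "dominant", tier, (v,), seg))
    return out


def _recessive_candidate(
    gene: PanelGene,
    variants: list[AnnotatedVariant],
    proband: str,
    pedigree: Pedigree | None,
    thresholds: MafThresholds,
) -> tuple[_Candidate | None, bool]:
    """Best recessive explanation for one gene, plus a flag for a lone het."""
    qualifying = []
    for v in variants:
        if not v.genotype(proband).carries(1):
            continue
        if not maf_filter(v, "recessive", thresholds):
            continue
        if assign_tier(v, gene) is None:
            continue
        qualifying.append(v)
    if not qualifying:
        return None, False
    if detect_genotype_pattern(qualifying, proband) != "biallelic":
        return None, True  # monoallelic hit in a recessive context

    hom = [v for v in qualifying if v.genotype(proband).is_hom_alt(1)]
    if hom:
        best = min(hom, key=lambda v: _TIER_RANK[assign_tier(v, gene)])
        causal = (best,)
    else:
        hets = sorted(
            (v for v in qualifying if v.genotype(proband).is_het),
            key=lambda v: (_TIER_RANK[assign_tier(v, gene)], v.key),
        )
        causal = tuple(hets[:2])
    # the explanation is only as strong as its weakest allele
    tier = TIERS[max(_TIER_RANK[assign_tier(v, gene)] for v in causal)]
    seg = check_segregation(list(causal), pedigree, "recessive")
    return _Candidate(gene, "recessive", tier, causal, seg), False


def classify_case(
    proband_id: str,
    variants: list[AnnotatedVariant],
    panel: list[PanelGene],
    pedigree: Pedigree | None = None,
    thresholds: MafThresholds | None = None,
    allow_unaffected_carriers: bool = False,
    mt_variants: list[tuple[int, str, str]] | None = None,
) -> CaseClassification:
    """Run the full cascade for one proband's consensus variants."""
    thresholds = thresholds or MafThresholds()
    if mt_variants is not None and lhon_screen(mt_variants) == "excluded":
        return CaseClassification(proband_id=proband_id, status="excluded_lhon")

    by_gene: dict[str, list[AnnotatedVariant]] = {}
    panel_by_symbol = {g.symbol: g for g in panel}
    for v in variants:
        if v.gene is None or v.gene not in panel_by_symbol:
            continue
        if v.clinical == "benign":
            continue
        by_gene.setdefault(v.gene, []).append(v)

    candidates: list[_Candidate] = []
    flags: set[str] = set()
    for symbol, gene_variants in sorted(by_gene.items()):
        gene = panel_by_symbol[symbol]
        dom: list[_Candidate] = []
        rec: _Candidate | None = None
        if "dominant" in gene.modes:
            dom = _dominant_candidates(
                gene, gene_variants, proband_id, pedigree, thresholds,
                allow_unaffected_carriers,
            )
        if "recessive" in gene.modes:
            rec, lone_het = _recessive_candidate(
                gene, gene_variants, proband_id, pedigree, thresholds
            )
            if lone_het and not dom:
                flags.add("monoallelic_recessive_hit")
        if rec is not None and dom:
            # both-mode gene with both patterns constructible: the biallelic
            # genotype explains the phenotype more completely, so the
            # gene's monoallelic candidates are withdrawn
            flags.add(f"both_modes_constructible:{symbol}")
            dom = []
        candidates.extend(dom)
        if rec is not None:
            candidates.append(rec)

    if not candidates:
        return CaseClassification(
            proband_id=proband_id, status="unsolved", flags=tuple(sorted(flags))
        )

    candidates.sort(key=lambda c: c.sort_key)
    best = candidates[0]
    ties = [
        c for c in candidates[1:]
        if c.sort_key[:2] == best.sort_key[:2] and c.gene.symbol != best.gene.symbol
    ]
    if ties:
        flags.add("ambiguous_gene:" + ",".join(sorted({c.gene.symbol for c in ties})))

    if best.tier == "T4_candidate_vus":
        status = "vus_candidate"
    else:
        status = "solved_dominant" if best.mode == "dominant" else "solved_recessive"
    return CaseClassification(
        proband_id=proband_id,
        status=status,
        gene=best.gene.symbol,
        mode=best.mode,
        tier=best.tier,
        causal_variants=tuple(v.key for v in best.variants),
        segregation=best.segregation,
        flags=tuple(sorted(flags | set(best.flags))),
    )
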