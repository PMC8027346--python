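"""The diagnostic cascade: LHON pre-screen, MAF filters, tier ladder,
biallelic detection, segregation, and the full per-case classification
checked against an independent rule oracle on a factorial of mini-cases."""

import itertools

import pytest

from ionprior.prioritize import (
    assign_tier,
    check_segregation,
    classify_case,
    detect_genotype_pattern,
    lhon_screen,
    maf_filter,
)
from ionprior.types import (
    AnnotatedVariant,
    Genotype,
    Individual,
    MafThresholds,
    NormalizedVariant,
    Pedigree,
)

P = "P1"


def av(gene, pos, consequence="missense", clinical=None, maf=None,
       gts=None, chrom=None):
    nv = NormalizedVariant(
        chrom=chrom or gene, pos=pos, ref="A", alt="C",
        genotypes=gts or {P: Genotype((0, 1))},
    )
    return AnnotatedVariant(
        variant=nv, gene=gene, consequence=consequence, maf=maf, clinical=clinical
    )


@pytest.fixture(scope="module")
def genes(toy_panel):
    return toy_panel[1]  # symbol -> PanelGene


class TestLhonScreen:
    def test_primary_mutation_excludes(self):
        assert lhon_screen([(11778, "G", "A")]) == "excluded"
        assert lhon_screen([(3460, "G", "A")]) == "excluded"
        assert lhon_screen([(14484, "T", "C")]) == "excluded"

    def test_empty_retained(self):
        assert lhon_screen([]) == "retained"

    def test_exact_allele_match_required(self):
        assert lhon_screen([(11778, "G", "C")]) == "retained"
        assert lhon_screen([(11779, "G", "A")]) == "retained"


class TestMafFilter:
    th = MafThresholds()

    def test_common_variant_fails_dominant(self):
        assert not maf_filter(av("OPA1", 10, maf=0.01), "dominant", self.th)

    def test_absent_maf_passes_both_modes(self):
        v = av("OPA1", 10, maf=None)
        assert maf_filter(v, "dominant", self.th)
        assert maf_filter(v, "recessive", self.th)

    def test_straddling_value_splits_modes(self):
        v = av("OPA1", 10, maf=0.001)
        assert not maf_filter(v, "dominant", self.th)
        assert maf_filter(v, "recessive", self.th)

    def test_boundaries_are_strict(self):
        assert not maf_filter(av("OPA1", 10, maf=0.0001), "dominant", self.th)
        assert not maf_filter(av("OPA1", 10, maf=0.005), "recessive", self.th)
        assert maf_filter(av("OPA1", 10, maf=0.0000999), "dominant", self.th)
        assert maf_filter(av("OPA1", 10, maf=0.00499), "recessive", self.th)

    def test_threshold_invariant_enforced(self):
        with pytest.raises(ValueError):
            MafThresholds(dominant_max=0.01, recessive_max=0.001)


class TestAssignTier:
    def test_reported_pathogenic_known_gene(self, genes):
        v = av("WFS1", 10, clinical="pathogenic")
        assert assign_tier(v, genes["WFS1"]) == "T1_reported_pathogenic"

    def test_novel_lof_known_gene(self, genes):
        v = av("OPA1", 10, consequence="nonsense")
        assert assign_tier(v, genes["OPA1"]) == "T2_novel_lof"

    def test_novel_missense_candidate_gene_is_vus(self, genes):
        v = av("CAND1", 10, consequence="missense")
        assert assign_tier(v, genes["CAND1"]) == "T4_candidate_vus"

    def test_benign_filtered(self, genes):
        v = av("OPA1", 10, consequence="nonsense", clinical="benign")
        assert assign_tier(v, genes["OPA1"]) is None

    def test_vus_catalogued_is_not_novel(self, genes):
        v = av("OPA1", 10, consequence="missense", clinical="vus")
        assert assign_tier(v, genes["OPA1"]) is None


class TestGenotypePattern:
    def test_hom_is_biallelic(self):
        v = av("TMEM126A", 10, gts={P: Genotype((1, 1))})
        assert detect_genotype_pattern([v], P) == "biallelic"

    def test_two_hets_presumed_compound(self):
        vs = [av("RTN4IP1", 10), av("RTN4IP1", 40)]
        assert detect_genotype_pattern(vs, P) == "biallelic"

    def test_single_het_monoallelic(self):
        assert detect_genotype_pattern([av("TMEM126A", 10)], P) == "monoallelic_het"

    def test_duplicate_key_not_biallelic(self):
        vs = [av("TMEM126A", 10), av("TMEM126A", 10)]
        assert detect_genotype_pattern(vs, P) == "monoallelic_het"


def trio(father_aff="no", mother_aff="no"):
    return Pedigree(
        family_id="F1",
        individuals=[
            Individual("dad", None, None, 1, father_aff),
            Individual("mom", None, None, 2, mother_aff),
            Individual(P, "dad", "mom", 1, "yes"),
        ],
        proband=P,
    )


class TestSegregation:
    def test_dominant_consistent(self):
        v = av("OPA1", 10, gts={P: Genotype((0, 1)), "dad": Genotype((0, 1)),
                                "mom": Genotype((0, 0))})
        assert check_segregation([v], trio(father_aff="yes"), "dominant") == "consistent"

    def test_dominant_affected_noncarrier_inconsistent(self):
        v = av("OPA1", 10, gts={P: Genotype((0, 1)), "dad": Genotype((0, 0)),
                                "mom": Genotype((0, 0))})
        assert check_segregation([v], trio(father_aff="yes"), "dominant") == "inconsistent"

    def test_dominant_unaffected_carrier_strict_vs_relaxed(self):
        v = av("OPA1", 10, gts={P: Genotype((0, 1)), "dad": Genotype((0, 1)),
                                "mom": Genotype((0, 0))})
        ped = trio()  # both parents unaffected
        assert check_segregation([v], ped, "dominant") == "inconsistent"
        assert (
            check_segregation([v], ped, "dominant", allow_unaffected_carriers=True)
            == "consistent"
        )

    def test_singleton_untested(self):
        v = av("OPA1", 10)
        singleton = Pedigree(
            "F1", [Individual(P, None, None, 1, "yes")], proband=P
        )
        assert check_segregation([v], singleton, "dominant") == "untested"
        assert check_segregation([v], None, "dominant") == "untested"

    def test_recessive_carrier_parents_consistent(self):
        k1 = av("TMEM126A", 10, gts={P: Genotype((0, 1)), "dad": Genotype((0, 1)),
                                     "mom": Genotype((0, 0))})
        k2 = av("TMEM126A", 40, gts={P: Genotype((0, 1)), "dad": Genotype((0, 0)),
                                     "mom": Genotype((0, 1))})
        assert check_segregation([k1, k2], trio(), "recessive") == "consistent"

    def test_recessive_cis_parent_refutes_compound_het(self):
        k1 = av("TMEM126A", 10, gts={P: Genotype((0, 1)), "dad": Genotype((0, 1)),
                                     "mom": Genotype((0, 0))})
        k2 = av("TMEM126A", 40, gts={P: Genotype((0, 1)), "dad": Genotype((0, 1)),
                                     "mom": Genotype((0, 0))})
        assert check_segregation([k1, k2], trio(), "recessive") == "inconsistent"

    def test_recessive_biallelic_unaffected_inconsistent(self):
        v = av("TMEM126A", 10, gts={P: Genotype((1, 1)), "dad": Genotype((1, 1)),
                                    "mom": Genotype((0, 1))})
        assert check_segregation([v], trio(), "recessive") == "inconsistent"


# ---------------------------------------------------------------------------
# classify_case: worked examples and the factorial rule-oracle comparison
# ---------------------------------------------------------------------------

class TestClassifyCase:
    def test_reported_pathogenic_het_opa1_solves_dominant(self, panel):
        v = av("OPA1", 200, clinical="pathogenic")
        c = classify_case(P, [v], panel)
        assert (c.status, c.gene, c.tier) == (
            "solved_dominant", "OPA1", "T1_reported_pathogenic",
        )
        assert c.causal_variants == (v.key,)

    def test_hom_nonsense_tmem126a_solves_recessive(self, panel):
        v = av("TMEM126A", 150, consequence="nonsense", gts={P: Genotype((1, 1))})
        c = classify_case(P, [v], panel)
        assert (c.status, c.gene, c.mode) == ("solved_recessive", "TMEM126A", "recessive")

    def test_lhon_positive_excluded_before_autosomal_analysis(self, panel):
        v = av("OPA1", 200, clinical="pathogenic")
        c = classify_case(P, [v], panel, mt_variants=[(11778, "G", "A")])
        assert c.status == "excluded_lhon"
        assert c.gene is None

    def test_lone_het_in_recessive_gene_flagged_unsolved(self, panel):
        v = av("TMEM126A", 150, consequence="nonsense")
        c = classify_case(P, [v], panel)
        assert c.status == "unsolved"
        assert "monoallelic_recessive_hit" in c.flags

    def test_biallelic_beats_monoallelic_in_both_mode_gene(self, panel):
        v1 = av("OPA1", 200, clinical="pathogenic")
        v2 = av("OPA1", 400, consequence="missense")
        c = classify_case(P, [v1, v2], panel)
        assert c.status == "solved_recessive"
        assert set(c.causal_variants) == {v1.key, v2.key}
        assert any(f.startswith("both_modes_constructible") for f in c.flags)

    def test_tier_dominance_adding_t1_never_downgrades(self, panel):
        base = [av("MFN2", 200, consequence="missense")]
        c0 = classify_case(P, base, panel)
        assert c0.tier == "T3_novel_missense"
        better = base + [av("AFG3L2", 100, clinical="pathogenic")]
        c1 = classify_case(P, better, panel)
        assert c1.tier == "T1_reported_pathogenic"
        assert c1.gene == "AFG3L2"

    def test_determinism(self, panel):
        vs = [av("OPA1", 200, clinical="pathogenic"), av("ACO2", 300, consequence="nonsense")]
        assert classify_case(P, vs, panel) == classify_case(P, list(reversed(vs)), panel)


def _oracle_tier(status_known, clinical, consequence):
    lof = consequence in ("nonsense", "frameshift", "splice")
    if clinical == "benign":
        return None
    if status_known:
        if clinical in ("pathogenic", "likely_pathogenic"):
            return 0
        if clinical is None:
            if lof:
                return 1
            if consequence == "missense":
                return 2
        return None
    if lof or consequence == "missense" or clinical in ("pathogenic", "likely_pathogenic"):
        return 3
    return None


def _oracle_classify(gene, variants):
    """Independent single-gene rule evaluation: (status, tier-index or None)."""
    known = gene.status == "known"

    def passes(maf, mode):
        lim = 0.0001 if mode == "dominant" else 0.005
        return maf is None or maf < lim

    dom_tiers = [
        _oracle_tier(known, cl, cons)
        for (cl, cons, maf, zyg) in variants
        if zyg == "het" and passes(maf, "dominant")
        and _oracle_tier(known, cl, cons) is not None
    ]
    rec_qual = [
        v for v in variants
        if passes(v[2], "recessive") and _oracle_tier(known, v[0], v[1]) is not None
    ]
    homs = [v for v in rec_qual if v[3] == "hom"]
    hets = [v for v in rec_qual if v[3] == "het"]
    rec_tier = None
    if "recessive" in gene.modes:
        if homs:
            rec_tier = min(_oracle_tier(known, v[0], v[1]) for v in homs)
        elif len(hets) >= 2:
            ts = sorted(_oracle_tier(known, v[0], v[1]) for v in hets)
            rec_tier = max(ts[:2])
    dom_tier = min(dom_tiers) if dom_tiers and "dominant" in gene.modes else None
    if rec_tier is not None:  # biallelic wins within the gene
        mode, tier = "recessive", rec_tier
    elif dom_tier is not None:
        mode, tier = "dominant", dom_tier
    else:
        lone = "recessive" in gene.modes and len(hets) == 1 and not homs
        return ("unsolved_flagged" if lone else "unsolved"), None
    if tier == 3:
        return "vus_candidate", tier
    return f"solved_{mode}", tier


def test_factorial_matches_rule_oracle(genes, panel):
    """Single-gene mini-cases over {clinical} x {consequence} x {zygosity
    pattern} x {MAF} x {gene kind} match the independent oracle."""
    tiers_map = {
        0: "T1_reported_pathogenic", 1: "T2_novel_lof",
        2: "T3_novel_missense", 3: "T4_candidate_vus",
    }
    gene_syms = ["MFN2", "TMEM126A", "OPA1", "CAND1"]
    clin_opts = [None, "pathogenic", "benign", "vus"]
    cons_opts = ["missense", "nonsense", "synonymous"]
    maf_opts = [None, 0.001, 0.05]
    zyg_patterns = [("het",), ("hom",), ("het", "het"), ("het", "hom")]
    n_checked = 0
    for sym, cl, cons, maf, pattern in itertools.product(
        gene_syms, clin_opts, cons_opts, maf_opts, zyg_patterns
    ):
        variants, desc = [], []
        for j, zyg in enumerate(pattern):
            gt = Genotype((1, 1)) if zyg == "hom" else Genotype((0, 1))
            variants.append(
                av(sym, 100 + 50 * j, consequence=cons, clinical=cl, maf=maf,
                   gts={P: gt})
            )
            desc.append((cl, cons, maf, zyg))
        got = classify_case(P, variants, panel)
        status, tier_idx = _oracle_classify(genes[sym], desc)
        if status == "unsolved_flagged":
            assert got.status == "unsolved"
            assert "monoallelic_recessive_hit" in got.flags
        else:
            assert got.status == status, (sym, cl, cons, maf, pattern)
            if tier_idx is not None:
                assert got.tier == tiers_map[tier_idx], (sym, cl, cons, maf, pattern)
                assert got.gene == sym
        n_checked += 1
    assert n_checked == len(gene_syms) * len(clin_opts) * len(cons_opts) * len(maf_opts) * len(zyg_patterns)
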