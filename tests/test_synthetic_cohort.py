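"""The synthetic cohort generator: noise channels, pedigree construction,
determinism, and end-to-end truth recovery through the pipeline."""

import numpy as np
import pytest
from scipy import stats

from ionprior import formats_io
from ionprior.consensus import CALLER_PRIORITY, build_consensus
from ionprior.normalize import normalize_all
from ionprior.pipeline import PipelineConfig, classify_family, recovery_rate, run_cohort
from ionprior.prioritize import check_segregation
from ionprior.synthetic_cohort import CohortSpec, generate
from ionprior.types import AnnotatedVariant, NormalizedVariant


def _spec(**kw):
    defaults = dict(n_probands=40, seed=9)
    defaults.update(kw)
    return CohortSpec(**defaults)


def _truth_keys(cohort):
    return {k for t in cohort.truth for k in t.variants}


class TestNoiseChannels:
    def test_noise_free_callers_contain_truth_exactly(self):
        cohort = generate(_spec(caller_sensitivity=1.0, jitter_prob=0.0, fp_rate=0.0,
                                background_rate=0.0))
        truth_by_fam = {}
        for t in cohort.truth:
            truth_by_fam.setdefault(t.family_id, set()).update(t.variants)
        for fam, by_caller in cohort.calls.items():
            expected = truth_by_fam.get(fam, set())
            for caller in CALLER_PRIORITY:
                got = {
                    (r.chrom, r.pos, r.ref, r.alts[0]) for r in by_caller[caller]
                }
                assert got == {tuple(k) for k in expected}, (fam, caller)

    def test_jitter_changes_raw_keys_but_not_normalized(self):
        cohort = generate(
            _spec(seed=21, n_probands=200, caller_sensitivity=1.0, jitter_prob=1.0,
                  fp_rate=0.0, background_rate=0.0)
        )
        truth_keys = _truth_keys(cohort)
        indel_truth = {k for k in truth_keys if len(k.ref) != len(k.alt)}
        assert indel_truth, "cohort must contain causal indels for this check"
        raw_mismatch = 0
        for fam, by_caller in cohort.calls.items():
            for caller, records in by_caller.items():
                raw = {(r.chrom, r.pos, r.ref, a) for r in records for a in r.alts}
                raw_mismatch += sum(1 for k in raw if tuple(k) not in {tuple(t) for t in truth_keys})
                normalized = normalize_all(records, cohort.reference)
                assert {v.key for v in normalized if any(
                    g.carries(1) for g in v.genotypes.values()
                )} <= truth_keys
        assert raw_mismatch > 0  # jitter actually re-expressed something

    def test_false_positives_are_single_caller_and_removed_by_consensus(self):
        cohort = generate(_spec(seed=5, caller_sensitivity=1.0, jitter_prob=0.0,
                                fp_rate=2.0, background_rate=0.0))
        truth_keys = _truth_keys(cohort)
        for fam, by_caller in cohort.calls.items():
            normalized = {
                c: normalize_all(rs, cohort.reference) for c, rs in by_caller.items()
            }
            merged = build_consensus(normalized, fam, min_support=2)
            for cv in merged:
                assert cv.key in truth_keys or len(cv.support) >= 2

    def test_same_seed_identical_output(self, tmp_path):
        a = generate(_spec(seed=33))
        b = generate(_spec(seed=33))
        assert [t.variants for t in a.truth] == [t.variants for t in b.truth]
        for fam in a.calls:
            assert a.calls[fam] == b.calls[fam]
        assert a.depth_track == b.depth_track
        da, db = tmp_path / "a", tmp_path / "b"
        a.write(da)
        b.write(db)
        for name in ("truth.tsv", "cohort.ped", "freq_table.tsv", "depth.tsv"):
            assert (da / name).read_bytes() == (db / name).read_bytes()

    def test_different_seed_differs(self):
        a = generate(_spec(seed=1))
        b = generate(_spec(seed=2))
        assert [t.variants for t in a.truth] != [t.variants for t in b.truth]


class TestPedigrees:
    def test_dominant_affected_parent_carries(self):
        cohort = generate(_spec(seed=13, n_probands=120, pedigree_fraction=1.0))
        checked = 0
        for t in cohort.truth:
            if t.mode != "dominant" or not t.has_pedigree:
                continue
            ped = cohort.pedigrees[t.family_id]
            affected_parents = [
                i for i in ped.relatives() if i.affected == "yes"
            ]
            assert len(affected_parents) == 1
            fam_calls = cohort.calls[t.family_id]
            carrier = affected_parents[0].iid
            for records in fam_calls.values():
                for r in records:
                    if (r.chrom, r.pos, r.ref, r.alts[0]) == tuple(t.variants[0]):
                        assert r.genotypes[carrier].carries(1)
                        checked += 1
        assert checked > 0

    def test_comphet_parents_carry_one_allele_each(self):
        cohort = generate(_spec(seed=17, n_probands=200, pedigree_fraction=1.0,
                                comphet_fraction=1.0))
        checked = 0
        for t in cohort.truth:
            if t.zygosity != "comphet" or not t.has_pedigree:
                continue
            ped = cohort.pedigrees[t.family_id]
            father, mother = ped.get(f"{t.proband_id}_f"), ped.get(f"{t.proband_id}_m")
            per_parent = {father.iid: set(), mother.iid: set()}
            for records in cohort.calls[t.family_id].values():
                for r in records:
                    key = (r.chrom, r.pos, r.ref, r.alts[0])
                    if key in {tuple(k) for k in t.variants}:
                        for parent in per_parent:
                            if r.genotypes.get(parent) and r.genotypes[parent].carries(1):
                                per_parent[parent].add(key)
            assert per_parent[father.iid] | per_parent[mother.iid] == {
                tuple(k) for k in t.variants
            }
            assert per_parent[father.iid].isdisjoint(per_parent[mother.iid])
            checked += 1
        assert checked > 0

    def test_injection_rate_one_makes_every_tested_family_inconsistent(self):
        cohort = generate(
            _spec(seed=29, n_probands=150, pedigree_fraction=1.0,
                  seg_inconsistency_rate=1.0, caller_sensitivity=1.0,
                  jitter_prob=0.0, fp_rate=0.0)
        )
        tested = 0
        for t in cohort.truth:
            if not t.has_pedigree:
                continue
            ped = cohort.pedigrees[t.family_id]
            variants = []
            for records in cohort.calls[t.family_id]["torrent_vc"]:
                key = (records.chrom, records.pos, records.ref, records.alts[0])
                if key in {tuple(k) for k in t.variants}:
                    nv = NormalizedVariant(
                        chrom=records.chrom, pos=records.pos, ref=records.ref,
                        alt=records.alts[0], genotypes=records.genotypes,
                    )
                    variants.append(
                        AnnotatedVariant(variant=nv, gene=t.gene, consequence="missense")
                    )
            assert variants
            assert check_segregation(variants, ped, t.mode) == "inconsistent"
            tested += 1
        assert tested > 0


class TestStatisticalStructure:
    def test_gene_frequencies_within_binomial_ci_moderate_n(self):
        cohort = generate(_spec(seed=3, n_probands=1500))
        dom = [t for t in cohort.truth if t.mode == "dominant"]
        counts = {}
        for t in dom:
            counts[t.gene] = counts.get(t.gene, 0) + 1
        weights = cohort.spec.dominant_gene_weights
        total_w = sum(weights.values())
        # simultaneous (Bonferroni) exact CIs to control the familywise rate
        alpha = 0.05 / len(weights)
        for gene, w in weights.items():
            ci = stats.binomtest(counts.get(gene, 0), len(dom)).proportion_ci(1 - alpha)
            assert ci.low <= w / total_w <= ci.high, gene

    def test_depth_track_low_fraction_near_spec(self):
        cohort = generate(_spec(seed=8))
        depths = np.array(list(cohort.depth_track.values()))
        frac_low = float((depths <= 25).mean())
        assert 0.02 <= frac_low <= 0.09  # target 0.05 with run-correlated noise

    def test_lhon_fraction_produces_exclusions(self):
        cohort = generate(_spec(seed=4, n_probands=60, lhon_fraction=0.2))
        cls, _ = run_cohort(cohort)
        excluded = [c for c in cls if c.status == "excluded_lhon"]
        carriers = [p for p, m in cohort.mt_variants.items() if m]
        assert {c.proband_id for c in excluded} == set(carriers)
        assert carriers


class TestEndToEnd:
    def test_noise_free_recovery_is_total(self):
        cohort = generate(_spec(seed=2, n_probands=150, caller_sensitivity=1.0,
                                jitter_prob=0.0, fp_rate=0.0))
        cls, _ = run_cohort(cohort)
        assert recovery_rate(cohort.truth, cls, cohort.panel) == 1.0

    def test_jitter_only_recovery_is_total(self):
        cohort = generate(_spec(seed=6, n_probands=150, caller_sensitivity=1.0,
                                jitter_prob=1.0, fp_rate=0.0))
        cls, _ = run_cohort(cohort)
        assert recovery_rate(cohort.truth, cls, cohort.panel) == 1.0

    def test_unsolved_probands_stay_unsolved(self):
        cohort = generate(_spec(seed=10, n_probands=100))
        cls, _ = run_cohort(cohort)
        truth_ids = {t.proband_id for t in cohort.truth}
        for c in cls:
            if c.proband_id not in truth_ids:
                assert c.status == "unsolved"

    def test_file_roundtrip_matches_in_memory_classification(self, tmp_path):
        cohort = generate(_spec(seed=12, n_probands=30))
        cls_mem, _ = run_cohort(cohort)
        cohort.write(tmp_path)
        reference = formats_io.read_fasta(tmp_path / "toy_reference.fa")
        panel = formats_io.read_panel(tmp_path / "panel_genes.tsv")
        transcripts = formats_io.read_transcripts(tmp_path / "transcripts.tsv")
        freq = formats_io.read_freq_table(tmp_path / "freq_table.tsv")
        clinical = formats_io.read_clinical_table(tmp_path / "clinical_table.tsv")
        peds = {p.family_id: p for p in formats_io.read_ped(tmp_path / "cohort.ped")}
        for c_mem in cls_mem[:10]:
            fam = cohort.family_of[c_mem.proband_id]
            calls = {
                caller: formats_io.read_vcf(
                    tmp_path / "vcf" / f"{fam}.{caller}.vcf", caller
                )
                for caller in CALLER_PRIORITY
            }
            c_file, _ = classify_family(
                c_mem.proband_id, calls, reference, panel, freq, clinical,
                transcripts, pedigree=peds.get(fam),
                config=PipelineConfig(),
            )
            assert c_file.status == c_mem.status
            assert c_file.gene == c_mem.gene
            assert set(c_file.causal_variants) == set(c_mem.causal_variants)

    def test_detection_rate_matches_binomial_tail(self):
        """Per-variant consensus detection under caller dropout p follows
        P(Bin(6, 1-p) >= m)."""
        p_drop, m = 0.2, 2
        cohort = generate(
            _spec(seed=31, n_probands=800, caller_sensitivity=1 - p_drop,
                  jitter_prob=0.0, fp_rate=0.0, background_rate=0.0,
                  pedigree_fraction=0.0)
        )
        detected = total = 0
        for t in cohort.truth:
            normalized = {
                c: normalize_all(rs, cohort.reference)
                for c, rs in cohort.calls[t.family_id].items()
            }
            merged = {cv.key for cv in build_consensus(normalized, t.family_id, m)}
            for k in t.variants:
                total += 1
                detected += k in merged
        expected = 1 - stats.binom.cdf(m - 1, 6, 1 - p_drop)
        se = np.sqrt(expected * (1 - expected) / total)
        assert total >= 150
        assert abs(detected / total - expected) <= 4 * se + 1e-9
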