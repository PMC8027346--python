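"""Cohort-level aggregation: diagnostic yield, per-gene frequencies by
inheritance mode, variant-class distribution and the OPA1 exon/domain
spectrum.

Counts are per proband (one classification each); the variant-class tally
is over *distinct* normalized variants, which is why a cohort can have more
solved probands than different variants (recurrent alleles).  Percentages
are reported to two decimals, shares within a mode summing to 100 up to
rounding.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

from .annotate import protein_position
from .types import AnnotatedVariant, CaseClassification, VariantKey

VARIANT_CLASSES = ("missense", "nonsense", "frameshift", "splice")


def _share(count: int, total: int) -> float:
    return round(100.0 * count / total, 2) if total else 0.0


@dataclass
class CohortSummary:
    n_total: int
    n_solved: int
    n_dominant: int
    n_recessive: int
    yield_pct: float
    dominant_pct: float  # of the whole cohort
    recessive_pct: float
    gene_counts: dict[str, dict[str, int]]  # mode -> gene -> probands
    gene_pct: dict[str, dict[str, float]]  # mode -> gene -> % of mode total
    n_distinct_variants: int
    class_counts: dict[str, int]
    class_pct: dict[str, float]
    n_vus_candidate: int = 0
    n_unsolved: int = 0
    flags: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        if self.n_solved != self.n_dominant + self.n_recessive:
            raise ValueError("n_solved must equal n_dominant + n_recessive")
        for mode, counts in self.gene_counts.items():
            total = {"dominant": self.n_dominant, "recessive": self.n_recessive}[mode]
            if sum(counts.values()) != total:
                raise ValueError(f"{mode} gene counts do not sum to the mode total")


def summarize(
    classifications: list[CaseClassification],
    distinct_variants: list[tuple[VariantKey, str]] | None = None,
    n_total: int | None = None,
    count_vus_as_solved: bool = False,
) -> CohortSummary:
    """Aggregate per-case classifications into the cohort summary.

    ``distinct_variants`` is a list of (normalized key, consequence class)
    pairs; duplicates are collapsed on the key.  ``n_total`` defaults to
    the number of classifications. Candidate-gene VUS cases count toward
    the solved totals only when ``count_vus_as_solved`` is set (they are
    tallied separately either way).
    """
    ids = [c.proband_id for c in classifications]
    if len(ids) != len(set(ids)):
        dup = next(i for i in ids if ids.count(i) > 1)
        raise ValueError(f"duplicate proband id {dup!r}")
    if n_total is None:
        n_total = len(classifications)
    if n_total < len(classifications):
        raise ValueError("cohort size smaller than number of classifications")

    solved = [c for c in classifications if c.solved]
    if count_vus_as_solved:
        solved += [c for c in classifications if c.status == "vus_candidate"]
    gene_counts: dict[str, Counter] = {"dominant": Counter(), "recessive": Counter()}
    for c in solved:
        gene_counts[c.mode][c.gene] += 1
    n_dom = sum(gene_counts["dominant"].values())
    n_rec = sum(gene_counts["recessive"].values())
    n_solved = n_dom + n_rec

    seen: dict[VariantKey, str] = {}
    for key, cls in distinct_variants or []:
        seen[VariantKey(*key)] = cls
    class_counts = Counter(seen.values())
    n_distinct = len(seen)

    mode_totals = {"dominant": n_dom, "recessive": n_rec}
    return CohortSummary(
        n_total=n_total,
        n_solved=n_solved,
        n_dominant=n_dom,
        n_recessive=n_rec,
        yield_pct=_share(n_solved, n_total),
        dominant_pct=_share(n_dom, n_total),
        recessive_pct=_share(n_rec, n_total),
        gene_counts={m: dict(c) for m, c in gene_counts.items()},
        gene_pct={
            m: {g: _share(n, mode_totals[m]) for g, n in c.items()}
            for m, c in gene_counts.items()
        },
        n_distinct_variants=n_distinct,
        class_counts={c: class_counts.get(c, 0) for c in VARIANT_CLASSES},
        class_pct={
            c: _share(class_counts.get(c, 0), n_distinct) for c in VARIANT_CLASSES
        },
        n_vus_candidate=sum(1 for c in classifications if c.status == "vus_candidate"),
        n_unsolved=sum(1 for c in classifications if c.status == "unsolved"),
    )


def classifications_from_counts(
    dominant_counts: dict[str, int],
    recessive_counts: dict[str, int],
    tier: str = "T1_reported_pathogenic",
) -> list[CaseClassification]:
    """Expand per-gene solved-proband count tables into minimal
    classification records (the reconstruction path for published cohort
    tables, where only the counts are available)."""
    out = []
    i = 0
    for mode, counts, status in (
        ("dominant", dominant_counts, "solved_dominant"),
        ("recessive", recessive_counts, "solved_recessive"),
    ):
        for gene, n in counts.items():
            for _ in range(n):
                i += 1
                out.append(
                    CaseClassification(
                        proband_id=f"case{i:04d}",
                        status=status,
                        gene=gene,
                        mode=mode,
                        tier=tier,
                    )
                )
    return out


@dataclass
class Opa1Spectrum:
    n_variants: int
    exon_counts: dict[int, int]
    class_counts: dict[str, int]
    class_pct: dict[str, float]
    domain_counts: dict[str, int]
    domain_pct: dict[str, float]


def opa1_spectrum(
    variants: list[AnnotatedVariant],
    domain_table: list[tuple[str, int, int]],
) -> Opa1Spectrum:
    """Exon, class and protein-domain distribution of distinct OPA1 variants.

    Domain attribution uses the protein position parsed from the simplified
    p. string; variants without a protein position (splice, frameshift
    without annotation) or outside the table's range go to 'other'.
    """
    distinct: dict[VariantKey, AnnotatedVariant] = {}
    for v in variants:
        if v.gene == "OPA1":
            distinct[v.key] = v
    vs = list(distinct.values())

    exon_counts = Counter(v.exon_number for v in vs if v.exon_number is not None)
    class_counts = Counter(v.consequence for v in vs if v.consequence in VARIANT_CLASSES)
    domain_counts: Counter = Counter()
    for v in vs:
        aa = protein_position(v.protein_change)
        name = "other"
        if aa is not None:
            for dom, s, e in domain_table:
                if s <= aa <= e:
                    name = dom
                    break
        domain_counts[name] += 1
    n = len(vs)
    return Opa1Spectrum(
        n_variants=n,
        exon_counts=dict(sorted(exon_counts.items())),
        class_counts={c: class_counts.get(c, 0) for c in VARIANT_CLASSES},
        class_pct={c: _share(class_counts.get(c, 0), n) for c in VARIANT_CLASSES},
        domain_counts=dict(domain_counts),
        domain_pct={d: _share(c, n) for d, c in domain_counts.items()},
    )
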