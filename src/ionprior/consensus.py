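"""Multi-caller consensus: merge normalized per-caller call sets.

Amplicon panels are conventionally called with several independent variant
callers and only sites reported by at least ``min_support`` of them are
retained, suppressing caller-specific artifacts while tolerating single
-caller dropout.  The caller set modelled here is the six-tool ensemble
used in targeted ION diagnostics (TorrentSuite VariantCaller, GATK
UnifiedGenotyper, VarScan2, SNVer, LoFreq, Platypus).

Genotypes are reconciled by majority vote over the supporting callers'
calls (het vs hom-alt); ties go to the highest-priority caller in
CALLER_PRIORITY order.
"""

from __future__ import annotations

from collections import defaultdict

from .normalize import is_normalized
from .types import ConsensusVariant, Genotype, NormalizedVariant, VariantKey

#: Fixed caller priority used for genotype tie-breaks (ensemble listing order).
CALLER_PRIORITY = (
    "torrent_vc",
    "gatk_ug",
    "varscan2",
    "snver",
    "lofreq",
    "platypus",
)


def caller_rank(caller: str) -> int:
    try:
        return CALLER_PRIORITY.index(caller)
    except ValueError:
        return len(CALLER_PRIORITY)  # unknown callers rank after the known six


def reconcile_genotype(genotypes_by_caller: dict[str, Genotype]) -> Genotype:
    """Majority vote over het / hom-alt calls; ties break by caller priority.

    Callers that reported the site but with a missing or hom-ref genotype do
    not vote.  If no caller votes the result is a missing genotype.
    """
    votes: dict[str, list[str]] = defaultdict(list)
    for caller, gt in genotypes_by_caller.items():
        if gt.is_missing or not gt.carries(1):
            continue
        cls = "hom_alt" if gt.is_hom_alt(1) else "het"
        votes[cls].append(caller)
    if not votes:
        return Genotype.missing()
    best = max(
        votes.items(),
        key=lambda kv: (len(kv[1]), -min(caller_rank(c) for c in kv[1])),
    )[0]
    return Genotype((1, 1)) if best == "hom_alt" else Genotype((0, 1))


def build_consensus(
    calls_by_caller: dict[str, list[NormalizedVariant]],
    sample_id: str,
    min_support: int = 2,
    reference: dict[str, str] | None = None,
    count_nonpass: bool = False,
) -> list[ConsensusVariant]:
    """Merge per-caller normalized call sets for one sample/family.

    A variant key counts as called by a caller when that caller emitted it
    with at least one sample carrying the alt allele (and, unless
    ``count_nonpass``, with FILTER PASS).  Keys supported by fewer than
    ``min_support`` callers are dropped.  ``calls_by_caller`` maps caller id
    → that caller's normalized variants; callers with no VCF for the sample
    should simply be absent from the map (they reduce ``n_callers_run``).

    When ``reference`` is given, every input is checked to be in canonical
    form and unnormalized input raises ValueError.
    """
    n_callers_run = len(calls_by_caller)
    if not 1 <= min_support <= max(n_callers_run, 1):
        raise ValueError(
            f"min_support {min_support} outside 1..{n_callers_run} callers run"
        )
    support: dict[VariantKey, set[str]] = defaultdict(set)
    gts: dict[VariantKey, dict[str, dict[str, Genotype]]] = defaultdict(dict)
    qual: dict[VariantKey, bool] = {}
    prov: dict[VariantKey, set] = defaultdict(set)
    for caller, calls in calls_by_caller.items():
        for v in calls:
            if reference is not None and not is_normalized(
                v.chrom, v.pos, v.ref, v.alt, reference
            ):
                raise ValueError(
                    f"unnormalized input from {caller}: {v.chrom}:{v.pos} {v.ref}>{v.alt}"
                )
            if not v.quality_pass and not count_nonpass:
                continue
            if not any(gt.carries(1) for gt in v.genotypes.values()):
                continue  # no sample carries the allele: not a call
            key = v.key
            support[key].add(caller)
            for sample, gt in v.genotypes.items():
                gts[key].setdefault(sample, {})[caller] = gt
            qual[key] = qual.get(key, True) and v.quality_pass
            prov[key] |= v.provenance
    out = []
    for key in sorted(support):
        if len(support[key]) < min_support:
            continue
        genotypes = {
            sample: reconcile_genotype(by_caller)
            for sample, by_caller in gts[key].items()
        }
        out.append(
            ConsensusVariant(
                key=key,
                sample_id=sample_id,
                support=frozenset(support[key]),
                genotypes=genotypes,
                n_callers_run=n_callers_run,
                quality_pass=qual[key],
                provenance=frozenset(prov[key]),
            )
        )
    return out
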