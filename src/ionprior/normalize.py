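"""Canonical variant representation: multiallelic decomposition and
left-aligned, parsimonious (trimmed) alleles.

Different variant callers legitimately emit the same underlying edit in
different coordinates — an indel placed at either end of a homopolymer run,
a SNV bundled into a multiallelic record — so calls are only comparable
after each allele is rewritten into a unique canonical form.  The form used
here is the standard one: biallelic; no shared proper suffix between ref
and alt; no shared proper prefix except the single anchor base an indel
needs to keep both alleles nonempty; and left-aligned, i.e. no
haplotype-equivalent representation exists at a smaller position.

The algorithm is the usual iterative right-trim / left-extend / left-trim
against the reference.  A ``max_shift`` cap bounds the leftward scan in
pathological repeat expanses; hitting the cap is an error, never a silent
stop.
"""

from __future__ import annotations

from .types import Genotype, NormalizedVariant, VariantRecord


class ReferenceMismatchError(ValueError):
    """The record's ref allele disagrees with the reference sequence."""


class MaxShiftExceededError(ValueError):
    """Left-alignment needed to scan further than max_shift bases."""


def decompose(record: VariantRecord) -> list[VariantRecord]:
    """Split a multiallelic record into one biallelic record per alt.

    For output k, genotype alleles pointing at alt k become allele 1;
    alleles pointing at the reference or any other alt become 0; missing
    stays missing.  Biallelic input is returned unchanged (as a one-element
    list).
    """
    if len(record.alts) == 1:
        return [record]
    out = []
    for k, alt in enumerate(record.alts, start=1):
        genotypes = {}
        for sample, gt in record.genotypes.items():
            mapped = tuple(
                -1 if a < 0 else (1 if a == k else 0) for a in gt.allele_indices
            )
            genotypes[sample] = Genotype(mapped, phased=gt.phased)
        out.append(
            VariantRecord(
                chrom=record.chrom,
                pos=record.pos,
                ref=record.ref,
                alts=(alt,),
                genotypes=genotypes,
                caller=record.caller,
                quality_pass=record.quality_pass,
            )
        )
    return out


def left_align_trim(
    chrom: str,
    pos: int,
    ref: str,
    alt: str,
    reference: str | dict[str, str],
    max_shift: int = 1000,
) -> tuple[int, str, str]:
    """Return the canonical (pos, ref, alt) for one biallelic variant.

    ``reference`` is either the contig sequence or a contig → sequence map.
    ``pos`` is 1-based.  Raises ReferenceMismatchError when ref does not
    match the reference at pos, MaxShiftExceededError when left-alignment
    would scan beyond ``max_shift`` bases.
    """
    seq = reference[chrom] if isinstance(reference, dict) else reference
    if ref != seq[pos - 1 : pos - 1 + len(ref)]:
        raise ReferenceMismatchError(
            f"{chrom}:{pos} ref {ref!r} != reference "
            f"{seq[pos - 1 : pos - 1 + len(ref)]!r}"
        )
    if ref == alt:
        raise ValueError(f"{chrom}:{pos}: ref == alt")
    start_pos = pos
    while True:
        # right-trim shared terminal base, left-extending first if an
        # allele would become empty
        if ref[-1] == alt[-1]:
            if len(ref) == 1 or len(alt) == 1:
                if pos == 1:
                    break  # cannot extend past the contig start
                if start_pos - (pos - 1) > max_shift:
                    raise MaxShiftExceededError(
                        f"{chrom}:{start_pos}: left-alignment exceeded max_shift={max_shift}"
                    )
                pos -= 1
                base = seq[pos - 1]
                ref = base + ref
                alt = base + alt
            ref = ref[:-1]
            alt = alt[:-1]
            continue
        break
    # left-trim shared leading bases while both alleles stay nonempty
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref = ref[1:]
        alt = alt[1:]
        pos += 1
    return pos, ref, alt


def normalize_record(
    record: VariantRecord,
    reference: str | dict[str, str],
    max_shift: int = 1000,
) -> list[NormalizedVariant]:
    """Decompose then left-align/trim one caller record."""
    out = []
    for sub in decompose(record):
        pos, ref, alt = left_align_trim(
            sub.chrom, sub.pos, sub.ref, sub.alts[0], reference, max_shift
        )
        out.append(
            NormalizedVariant(
                chrom=sub.chrom,
                pos=pos,
                ref=ref,
                alt=alt,
                genotypes=dict(sub.genotypes),
                provenance=frozenset(
                    {(record.caller, record.chrom, record.pos, record.ref, sub.alts[0])}
                ),
                quality_pass=record.quality_pass,
            )
        )
    return out


def normalize_all(
    records: list[VariantRecord],
    reference: str | dict[str, str],
    max_shift: int = 1000,
) -> list[NormalizedVariant]:
    out = []
    for rec in records:
        out.extend(normalize_record(rec, reference, max_shift))
    return out


def is_normalized(chrom: str, pos: int, ref: str, alt: str, reference) -> bool:
    """True iff (pos, ref, alt) is already in canonical form."""
    try:
        return (pos, ref, alt) == left_align_trim(chrom, pos, ref, alt, reference)
    except ValueError:
        return False


def apply_to_reference(seq: str, pos: int, ref: str, alt: str) -> str:
    """Haplotype obtained by applying the edit to a contig sequence (pos 1-based)."""
    if seq[pos - 1 : pos - 1 + len(ref)] != ref:
        raise ReferenceMismatchError(f"ref {ref!r} absent at pos {pos}")
    return seq[: pos - 1] + alt + seq[pos - 1 + len(ref) :]


def equivalent_representations(
    window: str, pos: int, ref: str, alt: str
) -> list[tuple[int, str, str]]:
    """Enumerate every (pos, ref, alt) within ``window`` that yields the same
    haplotype, with both alleles nonempty and ref != alt.

    Brute-force; intended for small windows (tests and the jitter engine of
    the synthetic cohort), not production-scale data.
    """
    hap = apply_to_reference(window, pos, ref, alt)
    n, m = len(window), len(hap)
    reps = []
    for p in range(1, n + 1):
        if window[: p - 1] != hap[: p - 1]:
            break
        for e in range(p - 1, n + 1):  # ref = window[p-1:e]
            alt_len = m - (n - e) - (p - 1)
            if alt_len < 1:
                continue
            r = window[p - 1 : e]
            a = hap[p - 1 : p - 1 + alt_len]
            if not r or r == a:
                continue
            if window[e:] == hap[p - 1 + alt_len :]:
                reps.append((p, r, a))
    return reps


def is_parsimonious(ref: str, alt: str, pos: int = 2) -> bool:
    """No shared terminal base (unless the variant sits at the contig start,
    where a right anchor is the only nonempty representation); no shared
    leading base unless one allele is the single anchor base."""
    if ref[-1] == alt[-1]:
        if len(ref) > 1 and len(alt) > 1:
            return False
        if pos > 1:  # could left-extend and right-trim instead
            return False
    if ref[0] == alt[0] and min(len(ref), len(alt)) > 1:
        return False
    return True


def canonical_by_enumeration(
    window: str, pos: int, ref: str, alt: str
) -> tuple[int, str, str]:
    """Independent canonical representative: the parsimonious equivalent
    representation at minimal position (then minimal allele lengths)."""
    reps = [
        r
        for r in equivalent_representations(window, pos, ref, alt)
        if is_parsimonious(r[1], r[2], r[0])
    ]
    return min(reps, key=lambda t: (t[0], len(t[1]), len(t[2])))
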