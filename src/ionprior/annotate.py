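"""Gene, consequence, population-frequency and clinical annotation.

This is a deliberately small, self-contained consequence engine over the
package's transcript models: SNVs inside the CDS are classified by
translating the affected codon (standard genetic code, reverse-complemented
internally for minus-strand genes); coding indels by net length modulo 3;
and any edit touching the two canonical intronic bases flanking an
exon-intron junction is a splice variant, overriding the other classes.
Population MAF and clinical significance come from packaged lookup tables
keyed by normalized variant identity.

Limitations by construction: no UTR or regulatory classes (the toy
transcripts are fully coding), no full HGVS (protein changes are simplified
``p.<ref><codon><alt>`` strings), and stop-loss is folded into missense.
"""

from __future__ import annotations

from Bio.Seq import Seq

from .types import (
    AnnotatedVariant,
    ClinicalTable,
    ConsensusVariant,
    FrequencyTable,
    NormalizedVariant,
    PanelGene,
    TranscriptModel,
    revcomp,
)

DEFAULT_SPLICE_WINDOW = 2


def _affected_span(v: NormalizedVariant) -> tuple[int, int]:
    """0-based half-open reference footprint actually changed by the edit.

    For normalized indels the shared anchor base is excluded; a pure
    insertion yields an empty span at the insertion point.
    """
    if v.is_snv:
        return v.pos - 1, v.pos
    if v.ref[0] == v.alt[0]:
        if len(v.ref) == 1:  # anchored insertion: empty span at the point
            return v.pos, v.pos  # inserted bases land at 0-based index pos
        return v.pos, v.pos - 1 + len(v.ref)  # anchored deletion/complex
    return v.pos - 1, v.pos - 1 + len(v.ref)


def _touches_splice(v: NormalizedVariant, tx: TranscriptModel, window: int) -> bool:
    s, e = _affected_span(v)
    for ws, we in tx.splice_windows(window):
        if s < e:  # substitution or deletion footprint
            if s < we and ws < e:
                return True
        else:  # insertion point: inserted bases land at 0-based index s
            if ws <= s < we:
                return True
    return False


def classify_consequence(
    v: NormalizedVariant,
    tx: TranscriptModel,
    reference: dict[str, str],
    splice_window: int = DEFAULT_SPLICE_WINDOW,
) -> tuple[str, str | None, int | None]:
    """Classify one normalized variant against one transcript.

    Returns (consequence, protein_change or None, exon_number or None).
    """
    if v.chrom != tx.chrom:
        raise ValueError(f"variant on {v.chrom} vs transcript {tx.gene} on {tx.chrom}")
    if _touches_splice(v, tx, splice_window):
        s, _ = _affected_span(v)
        return "splice", None, tx.exon_number_at(s) or tx.exon_number_at(s - 1)
    s, e = _affected_span(v)
    if s < e:  # substitution / deletion footprint intersects a coding exon?
        in_cds = any(cs < e and s < ce for cs, ce in tx.cds_exons)
    else:  # insertion point strictly inside a coding exon
        in_cds = any(cs < s <= ce for cs, ce in tx.cds_exons)

    if not in_cds:
        if tx.tx_start0 <= (s if s < e else s - 1) < tx.tx_end0:
            return "intronic", None, None
        return "intergenic", None, None

    if v.is_snv:
        cds_idx = tx.genomic_to_cds(v.pos - 1)
        if cds_idx is None:
            return "intronic", None, None
        cds = tx.spliced_cds(reference)
        codon_i = cds_idx // 3
        within = cds_idx % 3
        codon = cds[codon_i * 3 : codon_i * 3 + 3]
        alt_base = v.alt if tx.strand == "+" else revcomp(v.alt)
        new_codon = codon[:within] + alt_base + codon[within + 1 :]
        aa_ref = str(Seq(codon).translate())
        aa_alt = str(Seq(new_codon).translate())
        exon_n = tx.exon_number_at(v.pos - 1)
        pchange = f"p.{aa_ref}{codon_i + 1}{aa_alt}".replace("*", "X")
        if aa_alt == aa_ref:
            return "synonymous", pchange, exon_n
        if aa_alt == "*" and aa_ref != "*":
            return "nonsense", pchange, exon_n
        return "missense", pchange, exon_n

    # coding indel entirely inside the CDS
    net = len(v.alt) - len(v.ref)
    exon_n = tx.exon_number_at(s if s < e else s - 1)
    if net % 3 != 0:
        return "frameshift", None, exon_n
    return "inframe_indel", None, exon_n


def protein_position(change: str | None) -> int | None:
    """Codon number out of a simplified p. string, e.g. 'p.R55X' -> 55."""
    if not change or not change.startswith("p."):
        return None
    digits = "".join(c for c in change if c.isdigit())
    return int(digits) if digits else None


def annotate_variant(
    v: NormalizedVariant,
    panel: list[PanelGene],
    freq_table: FrequencyTable,
    clinical_table: ClinicalTable,
    transcripts: dict[str, TranscriptModel],
    reference: dict[str, str],
    splice_window: int = DEFAULT_SPLICE_WINDOW,
) -> AnnotatedVariant:
    """Attach gene, consequence, MAF and clinical significance.

    Gene assignment is by overlap of the variant footprint with the panel
    design regions; a variant overlapping several panel genes is annotated
    against the alphabetically first and flagged ambiguous.
    """
    s, e = _affected_span(v)
    qs, qe = (s, e) if s < e else (max(s - 1, 0), s + 1)
    hits = sorted(g.symbol for g in panel if g.overlaps(v.chrom, qs, qe))
    gene = hits[0] if hits else None

    consequence, pchange, exon_n = "intergenic", None, None
    tx = transcripts.get(gene) if gene else None
    if tx is None:
        # not on a panel gene: classify positionally against any transcript
        # sharing the contig, for the audit trail
        for cand in transcripts.values():
            if cand.chrom == v.chrom:
                tx = cand
                break
    if tx is not None and tx.chrom == v.chrom:
        consequence, pchange, exon_n = classify_consequence(v, tx, reference, splice_window)
        if gene is None and consequence not in ("intronic", "intergenic"):
            consequence = "intergenic"  # off-panel exonic hits are not interpreted

    return AnnotatedVariant(
        variant=v,
        gene=gene,
        consequence=consequence,
        maf=freq_table.maf(v.key),
        clinical=clinical_table.significance(v.key),
        exon_number=exon_n,
        protein_change=pchange,
        ambiguous_genes=tuple(hits[1:]),
    )


def consensus_to_normalized(cv: ConsensusVariant) -> NormalizedVariant:
    return NormalizedVariant(
        chrom=cv.key.chrom,
        pos=cv.key.pos,
        ref=cv.key.ref,
        alt=cv.key.alt,
        genotypes=dict(cv.genotypes),
        provenance=cv.provenance,
        quality_pass=cv.quality_pass,
    )


def annotate_consensus(
    consensus_variants: list[ConsensusVariant],
    panel: list[PanelGene],
    freq_table: FrequencyTable,
    clinical_table: ClinicalTable,
    transcripts: dict[str, TranscriptModel],
    reference: dict[str, str],
    splice_window: int = DEFAULT_SPLICE_WINDOW,
) -> list[AnnotatedVariant]:
    return [
        annotate_variant(
            consensus_to_normalized(cv),
            panel,
            freq_table,
            clinical_table,
            transcripts,
            reference,
            splice_window,
        )
        for cv in consensus_variants
    ]
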