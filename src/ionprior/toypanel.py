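"""Deterministic toy gene models for the 22-gene ION panel.

Real ION diagnostics runs on GRCh-coordinate transcripts; this package
instead ships one short synthetic contig per panel gene (2–4 exons, fully
coding CDS with canonical GT..AG introns) so every pipeline stage can be
exercised without reference downloads.  The builder is seeded with a fixed
internal constant: the toy panel is part of the package design, not a
per-run random object, and rebuilding it always yields byte-identical
sequences.

The 15 known genes and their inheritance modes follow the clinical ION
literature (OPA1/WFS1/ACO2/SPG7 act in both dominant and recessive forms);
the 7 CANDx placeholders stand in for unnamed candidate genes observed with
dominant segregation.
"""

from __future__ import annotations

import numpy as np

from .types import DNA, PanelGene, TranscriptModel, revcomp

_BUILD_SEED = 714  # fixed: the toy panel is a design artifact, not a sample

STOP_CODONS = ("TAA", "TAG", "TGA")

#: symbol -> (modes, status, strand, n_exons, n_coding_codons incl. start, excl. stop)
GENE_DESIGN: dict[str, tuple[tuple[str, ...], str, str, int, int]] = {
    "OPA1":      (("dominant", "recessive"), "known", "+", 4, 300),
    "OPA3":      (("dominant",), "known", "-", 2, 80),
    "WFS1":      (("dominant", "recessive"), "known", "+", 3, 200),
    "MFN2":      (("dominant",), "known", "+", 3, 160),
    "SPG7":      (("dominant", "recessive"), "known", "-", 3, 150),
    "AFG3L2":    (("dominant",), "known", "+", 3, 140),
    "DNM1L":     (("dominant",), "known", "+", 3, 140),
    "SSBP1":     (("dominant",), "known", "-", 2, 90),
    "MIEF1":     (("dominant",), "known", "+", 2, 100),
    "TMEM126A":  (("recessive",), "known", "+", 3, 100),
    "ACO2":      (("dominant", "recessive"), "known", "+", 3, 180),
    "RTN4IP1":   (("recessive",), "known", "-", 3, 120),
    "NDUFS2":    (("recessive",), "known", "+", 2, 110),
    "MCAT":      (("recessive",), "known", "+", 2, 90),
    "SLC25A46":  (("recessive",), "known", "-", 3, 110),
    "CAND1":     (("dominant",), "candidate", "+", 2, 70),
    "CAND2":     (("dominant",), "candidate", "+", 2, 70),
    "CAND3":     (("dominant",), "candidate", "-", 2, 70),
    "CAND4":     (("dominant",), "candidate", "+", 2, 70),
    "CAND5":     (("dominant",), "candidate", "+", 2, 70),
    "CAND6":     (("dominant",), "candidate", "-", 2, 70),
    "CAND7":     (("dominant",), "candidate", "+", 2, 70),
}

KNOWN_GENES = tuple(g for g, d in GENE_DESIGN.items() if d[1] == "known")
CANDIDATE_GENES = tuple(g for g, d in GENE_DESIGN.items() if d[1] == "candidate")

_FLANK = 120
_PANEL_PAD = 10  # design regions extend this far into introns/flanks

_NONSTOP_CODONS = tuple(
    a + b + c
    for a in DNA for b in DNA for c in DNA
    if a + b + c not in STOP_CODONS
)


def _random_cds(rng: np.random.Generator, n_codons: int) -> str:
    """Coding sequence: ATG, random non-stop codons (with guaranteed
    stop-gain-capable CGA/TGG sites), terminal TAA."""
    codons = ["ATG"]
    for i in range(1, n_codons):
        if i % 9 == 4:
            codons.append("CGA")  # one SNV away from TGA stop
        elif i % 9 == 8:
            codons.append("TGG")  # one SNV away from TGA/TAG
        else:
            codons.append(_NONSTOP_CODONS[rng.integers(len(_NONSTOP_CODONS))])
    codons.append("TAA")
    return "".join(codons)


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(DNA[i] for i in rng.integers(0, 4, size=n))


def _split_lengths(rng: np.random.Generator, total: int, parts: int) -> list[int]:
    """Split `total` into `parts` chunks of at least 30 bp each."""
    if parts == 1:
        return [total]
    cuts = sorted(rng.choice(np.arange(30, total - 30), size=parts - 1, replace=False))
    # enforce min spacing of 30 between cuts
    ok = [cuts[0]]
    for c in cuts[1:]:
        ok.append(max(c, ok[-1] + 30))
    lengths = []
    prev = 0
    for c in ok:
        lengths.append(c - prev)
        prev = c
    lengths.append(total - prev)
    return lengths


def build_gene(
    symbol: str, rng: np.random.Generator
) -> tuple[TranscriptModel, PanelGene, str]:
    """Build one toy gene; returns (transcript, panel entry, contig sequence)."""
    modes, status, strand, n_exons, n_codons = GENE_DESIGN[symbol]
    cds = _random_cds(rng, n_codons)
    exon_lens = _split_lengths(rng, len(cds), n_exons)
    intron_lens = [int(rng.integers(50, 91)) for _ in range(n_exons - 1)]

    # assemble in transcription orientation first
    tx_parts: list[str] = []
    offset = 0
    for i, el in enumerate(exon_lens):
        tx_parts.append(cds[offset : offset + el])
        offset += el
        if i < n_exons - 1:
            tx_parts.append("GT" + _random_seq(rng, intron_lens[i] - 4) + "AG")
    tx_seq = "".join(tx_parts)
    left = _random_seq(rng, _FLANK)
    right = _random_seq(rng, _FLANK)
    genomic_tx = tx_seq if strand == "+" else revcomp(tx_seq)
    contig = left + genomic_tx + right

    # exon coordinates on the forward genomic strand
    exons_tx: list[tuple[int, int]] = []
    pos = _FLANK
    for i, el in enumerate(exon_lens):
        exons_tx.append((pos, pos + el))
        pos += el
        if i < n_exons - 1:
            pos += intron_lens[i]
    if strand == "+":
        exons = exons_tx
    else:
        total = len(contig)
        exons = sorted((total - e, total - s) for s, e in exons_tx)

    tx = TranscriptModel(
        gene=symbol,
        chrom=symbol,
        strand=strand,
        exons=exons,
        cds_start0=exons[0][0],
        cds_end0=exons[-1][1],
    )
    panel = PanelGene(
        symbol=symbol,
        modes=frozenset(modes),
        status=status,
        regions=[
            (symbol, max(0, s - _PANEL_PAD), min(len(contig), e + _PANEL_PAD))
            for s, e in exons
        ],
    )
    return tx, panel, contig


def build_toy_panel() -> tuple[
    dict[str, TranscriptModel], dict[str, PanelGene], dict[str, str]
]:
    """Build all 22 toy genes deterministically.

    Returns (transcripts, panel genes, reference) keyed by gene symbol; the
    reference maps contig name → sequence.
    """
    rng = np.random.default_rng(_BUILD_SEED)
    transcripts: dict[str, TranscriptModel] = {}
    panel: dict[str, PanelGene] = {}
    reference: dict[str, str] = {}
    for symbol in GENE_DESIGN:
        tx, pg, contig = build_gene(symbol, rng)
        transcripts[symbol] = tx
        panel[symbol] = pg
        reference[symbol] = contig
    return transcripts, panel, reference


#: Approximate OPA1 domain layout scaled to the 300-aa toy protein
#: (GTPase / central dynamin / GTPase-effector domains); configuration,
#: not biology — real residue ranges must be supplied for real data.
OPA1_TOY_DOMAINS: list[tuple[str, int, int]] = [
    ("N-terminal", 1, 59),
    ("GTPase", 60, 160),
    ("central_dynamin", 161, 250),
    ("GED", 251, 290),
]
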