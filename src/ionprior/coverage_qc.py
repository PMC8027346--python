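"""Per-base coverage statistics over the panel design and the Sanger
backfill list for under-covered regions.

Amplicon panels leave a handful of first exons and GC-rich segments
under-sequenced; clinical practice is to report the fraction of design
bases above fixed depth thresholds (25x/50x/100x) and to re-sequence by
Sanger any design interval whose depth stays at or below a floor.
"""

from __future__ import annotations

from collections import defaultdict

import numpy as np

from .types import PanelGene, TranscriptModel

DepthTrack = dict[tuple[str, int], int]  # (chrom, 1-based pos) -> depth


def design_positions(panel: list[PanelGene]) -> list[tuple[str, int]]:
    """All (chrom, 1-based pos) bases covered by the panel design."""
    out = []
    for gene in panel:
        for chrom, s0, e0 in gene.regions:
            out.extend((chrom, p) for p in range(s0 + 1, e0 + 1))
    return sorted(set(out))


def coverage_fractions(
    track: DepthTrack,
    thresholds: list[int] = (25, 50, 100),
    strictly_greater: bool = True,
) -> dict[int, float]:
    """Fraction of tracked design bases with depth above each threshold.

    The comparison is strict (> t) by default; ``strictly_greater=False``
    switches to >= t.
    """
    if not track:
        raise ValueError("empty depth track")
    depths = np.fromiter(track.values(), dtype=np.int64)
    out = {}
    for t in thresholds:
        hits = (depths > t) if strictly_greater else (depths >= t)
        out[int(t)] = float(hits.mean())
    return out


def backfill_regions(
    track: DepthTrack,
    panel: list[PanelGene],
    transcripts: dict[str, TranscriptModel] | None = None,
    min_depth: int = 25,
) -> list[tuple[str, int, int, str]]:
    """Maximal merged intervals of design bases with depth <= min_depth.

    Design bases absent from the track count as depth 0.  Returns BED-style
    (chrom, start0, end0, label) with the label naming the overlapping gene
    and, when transcript models are available, the exon number.
    """
    if min_depth < 1:
        raise ValueError("min_depth must be >= 1")
    low_by_chrom: dict[str, list[int]] = defaultdict(list)
    for chrom, pos in design_positions(panel):
        if track.get((chrom, pos), 0) <= min_depth:
            low_by_chrom[chrom].append(pos)

    intervals: list[tuple[str, int, int]] = []
    for chrom in sorted(low_by_chrom):
        run_start = prev = None
        for pos in sorted(low_by_chrom[chrom]):
            if prev is not None and pos == prev + 1:
                prev = pos
                continue
            if run_start is not None:
                intervals.append((chrom, run_start - 1, prev))
            run_start = prev = pos
        if run_start is not None:
            intervals.append((chrom, run_start - 1, prev))

    labeled = []
    for chrom, s0, e0 in intervals:
        genes = [g for g in panel if g.overlaps(chrom, s0, e0)]
        label_parts = []
        for g in genes:
            exons: set[int] = set()
            tx = (transcripts or {}).get(g.symbol)
            if tx is not None and tx.chrom == chrom:
                for p0 in range(s0, e0):
                    n = tx.exon_number_at(p0)
                    if n is not None:
                        exons.add(n)
            if exons:
                label_parts.append(
                    f"{g.symbol}:exon" + ",".join(str(n) for n in sorted(exons))
                )
            else:
                label_parts.append(g.symbol)
        labeled.append((chrom, s0, e0, ";".join(label_parts)))
    return labeled
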