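"""Readers and writers for every external format the pipeline touches.

VCF handling goes through :mod:`pysam`; the dialect supported is the
VCFv4.2 subset the six upstream callers actually emit for amplicon panels
(CHROM POS ID REF ALT QUAL FILTER INFO FORMAT + samples, GT required; no
symbolic alleles or breakends).  Genomic intervals are 1-based inclusive in
files and 0-based half-open in memory; every conversion is centralized
here.

Records whose FILTER is neither ``PASS`` nor ``.`` are retained with
``quality_pass=False`` rather than dropped, so the consensus stage can
decide whether to count them.
"""

from __future__ import annotations

import warnings
from importlib import resources
from pathlib import Path

import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .types import (
    ClinicalTable,
    FrequencyTable,
    Genotype,
    Individual,
    PanelGene,
    Pedigree,
    TranscriptModel,
    VariantRecord,
)


class FormatError(ValueError):
    """Raised when an input file violates the supported dialect."""


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def _genotype_from_pysam(sample) -> Genotype:
    gt = sample.get("GT")
    if gt is None or len(gt) == 0 or all(a is None for a in gt):
        return Genotype.missing()
    alleles = tuple(-1 if a is None else int(a) for a in gt)
    if len(alleles) == 1:  # haploid (e.g. mtDNA): represent as homoplasmic
        alleles = (alleles[0], alleles[0])
    return Genotype(alleles[:2], phased=bool(sample.phased))


def read_vcf(path: str | Path, caller: str) -> list[VariantRecord]:
    """Parse a VCF into VariantRecords tagged with the emitting caller."""
    records: list[VariantRecord] = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # pysam warns on contigs absent from header
        try:
            vf = pysam.VariantFile(str(path))
        except (ValueError, OSError) as exc:
            raise FormatError(f"{path}: not a parseable VCF: {exc}") from exc
        with vf:
            for i, rec in enumerate(vf.fetch() if vf.index else vf, start=1):
                if "GT" not in rec.format:
                    raise FormatError(f"{path}: record {i} ({rec.chrom}:{rec.pos}): missing GT")
                if rec.alts is None:
                    raise FormatError(f"{path}: record {i}: missing ALT")
                filters = list(rec.filter.keys())
                quality_pass = filters in ([], ["PASS"])
                genotypes = {
                    name: _genotype_from_pysam(sample)
                    for name, sample in rec.samples.items()
                }
                try:
                    records.append(
                        VariantRecord(
                            chrom=rec.chrom,
                            pos=rec.pos,
                            ref=rec.ref,
                            alts=tuple(rec.alts),
                            genotypes=genotypes,
                            caller=caller,
                            quality_pass=quality_pass,
                        )
                    )
                except ValueError as exc:
                    raise FormatError(f"{path}: record {i}: {exc}") from exc
    return records


def write_vcf(
    path: str | Path,
    records: list[VariantRecord],
    samples: list[str],
    contig_lengths: dict[str, int] | None = None,
    info: dict[int, dict[str, str]] | None = None,
) -> None:
    """Write VariantRecords as an uncompressed VCF.

    ``info`` optionally maps record index → INFO key/value strings (used by
    the consensus stage for SUP= and CALLERS=).
    """
    header = pysam.VariantHeader()
    if contig_lengths is None:
        contig_lengths = {}
        for rec in records:
            need = rec.pos + len(rec.ref) + 1000
            contig_lengths[rec.chrom] = max(contig_lengths.get(rec.chrom, 0), need)
    for chrom, length in contig_lengths.items():
        header.contigs.add(chrom, length=length)
    header.formats.add("GT", 1, "String", "Genotype")
    header.filters.add("LowQual", None, None, "Failed caller quality filter")
    if info:
        keys = {k for kv in info.values() for k in kv}
        for k in sorted(keys):
            header.info.add(k, 1, "String", k)
    for s in samples:
        header.add_sample(s)
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for i, rec in enumerate(records):
            vrec = out.new_record(
                contig=rec.chrom,
                start=rec.pos - 1,
                alleles=(rec.ref, *rec.alts),
            )
            vrec.filter.add("PASS" if rec.quality_pass else "LowQual")
            if info and i in info:
                for k, v in info[i].items():
                    vrec.info[k] = v
            for s in samples:
                gt = rec.genotypes.get(s, Genotype.missing())
                vrec.samples[s]["GT"] = tuple(
                    None if a < 0 else a for a in gt.allele_indices
                )
                vrec.samples[s].phased = gt.phased
            out.write(vrec)


# ---------------------------------------------------------------------------
# PED
# ---------------------------------------------------------------------------

_AFFECTED = {"2": "yes", "1": "no", "0": "unknown", "-9": "unknown"}


def read_ped(path: str | Path) -> list[Pedigree]:
    """Parse a 6-column PED file into one Pedigree per family.

    The proband is the first affected individual listed in the family; a
    family with no affected member gets proband=None with a warning.
    """
    families: dict[str, list[Individual]] = {}
    order: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 6:
                raise FormatError(f"{path}:{lineno}: expected 6 PED columns, got {len(fields)}")
            fam, iid, father, mother, sex, pheno = fields[:6]
            if pheno not in _AFFECTED:
                raise FormatError(f"{path}:{lineno}: bad phenotype code {pheno!r}")
            ind = Individual(
                iid=iid,
                father=None if father == "0" else father,
                mother=None if mother == "0" else mother,
                sex=int(sex) if sex in ("0", "1", "2") else 0,
                affected=_AFFECTED[pheno],
            )
            if fam not in families:
                families[fam] = []
                order.append(fam)
            families[fam].append(ind)

    pedigrees = []
    for fam in order:
        inds = families[fam]
        affected = [i.iid for i in inds if i.affected == "yes"]
        if not affected:
            warnings.warn(f"family {fam}: no affected individual; proband unset")
        try:
            pedigrees.append(
                Pedigree(family_id=fam, individuals=inds, proband=affected[0] if affected else None)
            )
        except ValueError as exc:
            raise FormatError(f"{path}: family {fam}: {exc}") from exc
    return pedigrees


def write_ped(path: str | Path, pedigrees: list[Pedigree]) -> None:
    rev = {"yes": "2", "no": "1", "unknown": "0"}
    with open(path, "w") as fh:
        for ped in pedigrees:
            for ind in ped.individuals:
                fh.write(
                    f"{ped.family_id}\t{ind.iid}\t{ind.father or 0}\t"
                    f"{ind.mother or 0}\t{ind.sex}\t{rev[ind.affected]}\n"
                )


# ---------------------------------------------------------------------------
# BED (panel design)
# ---------------------------------------------------------------------------

def read_bed(path: str | Path) -> list[tuple[str, int, int, str]]:
    """BED intervals as (chrom, start0, end0, name); name '' if absent."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: BED needs >=3 columns")
            out.append(
                (fields[0], int(fields[1]), int(fields[2]), fields[3] if len(fields) > 3 else "")
            )
    return out


def write_bed(path: str | Path, intervals: list[tuple[str, int, int, str]]) -> None:
    with open(path, "w") as fh:
        for chrom, s, e, name in intervals:
            fh.write(f"{chrom}\t{s}\t{e}\t{name}\n")


# ---------------------------------------------------------------------------
# TSV tables
# ---------------------------------------------------------------------------

def _region_str(region: tuple[str, int, int]) -> str:
    chrom, s0, e0 = region
    return f"{chrom}:{s0 + 1}-{e0}"  # 1-based inclusive externally


def _parse_region(text: str) -> tuple[str, int, int]:
    chrom, span = text.split(":")
    s, e = span.split("-")
    return chrom, int(s) - 1, int(e)


def read_panel(path: str | Path) -> list[PanelGene]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"symbol", "modes", "status", "regions"}
    if not required.issubset(df.columns):
        raise FormatError(f"{path}: panel table needs columns {sorted(required)}")
    if df["symbol"].duplicated().any():
        dup = df.loc[df["symbol"].duplicated(), "symbol"].iloc[0]
        raise FormatError(f"{path}: duplicate gene symbol {dup!r}")
    genes = []
    for _, row in df.iterrows():
        try:
            genes.append(
                PanelGene(
                    symbol=row["symbol"],
                    modes=frozenset(row["modes"].split(",")),
                    status=row["status"],
                    regions=[_parse_region(r) for r in row["regions"].split(";")],
                )
            )
        except ValueError as exc:
            raise FormatError(f"{path}: gene {row['symbol']}: {exc}") from exc
    return genes


def write_panel(path: str | Path, genes: list[PanelGene]) -> None:
    rows = [
        {
            "symbol": g.symbol,
            "modes": ",".join(sorted(g.modes)),
            "status": g.status,
            "regions": ";".join(_region_str(r) for r in g.regions),
        }
        for g in genes
    ]
    pd.DataFrame(rows, columns=["symbol", "modes", "status", "regions"]).to_csv(
        path, sep="\t", index=False
    )


def read_freq_table(path: str | Path) -> FrequencyTable:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "pos": int, "ref": str, "alt": str, "maf": float})
    table = FrequencyTable()
    for _, row in df.iterrows():
        table[(row["chrom"], int(row["pos"]), row["ref"], row["alt"])] = row["maf"]
    return table


def write_freq_table(path: str | Path, table: FrequencyTable) -> None:
    rows = [
        {"chrom": k.chrom, "pos": k.pos, "ref": k.ref, "alt": k.alt, "maf": v}
        for k, v in sorted(table.items())
    ]
    pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt", "maf"]).to_csv(
        path, sep="\t", index=False
    )


def read_clinical_table(path: str | Path) -> ClinicalTable:
    df = pd.read_csv(path, sep="\t", dtype=str)
    table = ClinicalTable()
    for _, row in df.iterrows():
        try:
            table[(row["chrom"], int(row["pos"]), row["ref"], row["alt"])] = row["significance"]
        except ValueError as exc:
            raise FormatError(f"{path}: {exc}") from exc
    return table


def write_clinical_table(path: str | Path, table: ClinicalTable) -> None:
    rows = [
        {"chrom": k.chrom, "pos": k.pos, "ref": k.ref, "alt": k.alt, "significance": v}
        for k, v in sorted(table.items())
    ]
    pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt", "significance"]).to_csv(
        path, sep="\t", index=False
    )


def read_transcripts(path: str | Path) -> dict[str, TranscriptModel]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    models = {}
    for _, row in df.iterrows():
        exons = []
        for span in row["exons"].split(","):
            s, e = span.split("-")
            exons.append((int(s) - 1, int(e)))
        models[row["gene"]] = TranscriptModel(
            gene=row["gene"],
            chrom=row["chrom"],
            strand=row["strand"],
            exons=exons,
            cds_start0=int(row["cds_start"]) - 1,
            cds_end0=int(row["cds_end"]),
        )
    return models


def write_transcripts(path: str | Path, models: dict[str, TranscriptModel]) -> None:
    rows = [
        {
            "gene": t.gene,
            "chrom": t.chrom,
            "strand": t.strand,
            "exons": ",".join(f"{s + 1}-{e}" for s, e in t.exons),
            "cds_start": t.cds_start0 + 1,
            "cds_end": t.cds_end0,
        }
        for t in models.values()
    ]
    pd.DataFrame(rows, columns=["gene", "chrom", "strand", "exons", "cds_start", "cds_end"]).to_csv(
        path, sep="\t", index=False
    )


def read_domain_table(path: str | Path) -> list[tuple[str, int, int]]:
    """OPA1 protein domain table: (name, aa_start, aa_end), 1-based inclusive."""
    df = pd.read_csv(path, sep="\t", dtype={"domain": str, "aa_start": int, "aa_end": int})
    domains = [(r["domain"], int(r["aa_start"]), int(r["aa_end"])) for _, r in df.iterrows()]
    prev_end = 0
    for name, s, e in domains:
        if s <= prev_end or e < s:
            raise FormatError(f"{path}: domain intervals must be ascending and non-overlapping")
        prev_end = e
    return domains


def write_domain_table(path: str | Path, domains: list[tuple[str, int, int]]) -> None:
    pd.DataFrame(
        [{"domain": n, "aa_start": s, "aa_end": e} for n, s, e in domains],
        columns=["domain", "aa_start", "aa_end"],
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Per-case classification table
# ---------------------------------------------------------------------------

def write_classifications(path: str | Path, classifications) -> None:
    from .types import CaseClassification  # noqa: F401  (documentation import)

    rows = []
    for c in classifications:
        rows.append(
            {
                "proband": c.proband_id,
                "status": c.status,
                "gene": c.gene or "",
                "mode": c.mode or "",
                "tier": c.tier or "",
                "causal_variants": ";".join(
                    f"{k.chrom}:{k.pos}:{k.ref}:{k.alt}" for k in c.causal_variants
                ),
                "segregation": c.segregation,
                "flags": ",".join(c.flags),
            }
        )
    pd.DataFrame(
        rows,
        columns=[
            "proband", "status", "gene", "mode", "tier",
            "causal_variants", "segregation", "flags",
        ],
    ).to_csv(path, sep="\t", index=False)


def read_classifications(path: str | Path):
    from .types import CaseClassification, VariantKey

    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    out = []
    for _, r in df.iterrows():
        keys = []
        for item in r["causal_variants"].split(";"):
            if item:
                chrom, pos, ref, alt = item.split(":")
                keys.append(VariantKey(chrom, int(pos), ref, alt))
        out.append(
            CaseClassification(
                proband_id=r["proband"],
                status=r["status"],
                gene=r["gene"] or None,
                mode=r["mode"] or None,
                tier=r["tier"] or None,
                causal_variants=tuple(keys),
                segregation=r["segregation"],
                flags=tuple(f for f in r["flags"].split(",") if f),
            )
        )
    return out


# ---------------------------------------------------------------------------
# Depth track + FASTA
# ---------------------------------------------------------------------------

def read_depth_tsv(path: str | Path) -> dict[tuple[str, int], int]:
    """samtools-depth-style 3-column text: chrom, pos (1-based), depth."""
    df = pd.read_csv(
        path, sep="\t", header=None, names=["chrom", "pos", "depth"],
        dtype={"chrom": str, "pos": int, "depth": int}, comment="#",
    )
    if (df["depth"] < 0).any():
        raise FormatError(f"{path}: negative depth")
    return {(r.chrom, int(r.pos)): int(r.depth) for r in df.itertuples()}


def write_depth_tsv(path: str | Path, track: dict[tuple[str, int], int]) -> None:
    with open(path, "w") as fh:
        for (chrom, pos), depth in sorted(track.items()):
            fh.write(f"{chrom}\t{pos}\t{depth}\n")


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(path: str | Path, seqs: dict[str, str]) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# Packaged default tables
# ---------------------------------------------------------------------------

def _data_path(name: str):
    return resources.files("ionprior.data").joinpath(name)


def load_default_panel() -> list[PanelGene]:
    return read_panel(_data_path("panel_genes.tsv"))


def load_default_transcripts() -> dict[str, TranscriptModel]:
    return read_transcripts(_data_path("transcripts.tsv"))


def load_default_reference() -> dict[str, str]:
    return read_fasta(_data_path("toy_reference.fa"))


def load_default_domains() -> list[tuple[str, int, int]]:
    return read_domain_table(_data_path("opa1_domains.tsv"))


def load_default_clinical() -> ClinicalTable:
    return read_clinical_table(_data_path("clinical_table.tsv"))


def load_default_freq() -> FrequencyTable:
    return read_freq_table(_data_path("freq_table.tsv"))
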