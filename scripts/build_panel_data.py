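"""Regenerate the packaged toy panel data files (deterministic).

Run from the repository root:

    python scripts/build_panel_data.py
"""

from pathlib import Path

from ionprior import formats_io
from ionprior.toypanel import OPA1_TOY_DOMAINS, build_toy_panel
from ionprior.types import ClinicalTable, FrequencyTable

DATA = Path(__file__).resolve().parents[1] / "src" / "ionprior" / "data"


def main() -> None:
    transcripts, panel, reference = build_toy_panel()
    DATA.mkdir(parents=True, exist_ok=True)
    formats_io.write_fasta(DATA / "toy_reference.fa", reference)
    formats_io.write_panel(DATA / "panel_genes.tsv", list(panel.values()))
    formats_io.write_transcripts(DATA / "transcripts.tsv", transcripts)
    formats_io.write_domain_table(DATA / "opa1_domains.tsv", OPA1_TOY_DOMAINS)

    # small demonstration catalogs: one recurrent reported-pathogenic
    # nonsense in TMEM126A and a reported missense in WFS1, plus two common
    # benign alleles with population frequencies
    from ionprior.synthetic_cohort import _SiteFactory
    import numpy as np

    rng = np.random.default_rng(20)
    clinical = ClinicalTable()
    freq = FrequencyTable()
    for gene, cls in (("TMEM126A", "nonsense"), ("WFS1", "missense")):
        key = _SiteFactory(transcripts[gene], reference, rng).draw(cls)
        clinical[key] = "pathogenic"
    for gene in ("OPA1", "ACO2"):
        fac = _SiteFactory(transcripts[gene], reference, rng)
        key = fac.draw("missense")
        freq[key] = round(float(rng.uniform(0.01, 0.1)), 4)
        clinical[key] = "benign"
    formats_io.write_clinical_table(DATA / "clinical_table.tsv", clinical)
    formats_io.write_freq_table(DATA / "freq_table.tsv", freq)
    print(f"wrote packaged tables to {DATA}")


if __name__ == "__main__":
    main()
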