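"""TSV (and optional VCF) readers/writers for the pipeline's tables.

All tabular interchange is plain TSV via pandas: the SNP panel, per-site
allele counts, MAF-like somatic variant tables, sample manifests, and the
per-sample report tables the CLI emits. Simulated variant sets can also be
exported as VCF with the allele fraction in the standard AF INFO field.
"""

from __future__ import annotations

import pandas as pd

PANEL_COLUMNS = ["site_id", "chrom", "pos", "ref_allele", "alt_allele", "pop_alt_freq"]
COUNT_COLUMNS = ["site_id", "depth", "ref_count", "alt_count", "other_count"]
VARIANT_COLUMNS = [
    "gene", "chrom", "pos", "ref", "alt", "vaf", "nonsynonymous", "oncokb_level",
]


def _read(path, required) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(required) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return df


def read_panel(path) -> pd.DataFrame:
    return _read(path, PANEL_COLUMNS)


def write_panel(panel: pd.DataFrame, path) -> None:
    panel[PANEL_COLUMNS].to_csv(path, sep="\t", index=False)


def read_allele_counts(path) -> pd.DataFrame:
    return _read(path, COUNT_COLUMNS)


def write_allele_counts(counts: pd.DataFrame, path) -> None:
    counts[COUNT_COLUMNS].to_csv(path, sep="\t", index=False)


def read_variants(path) -> pd.DataFrame:
    return _read(path, ["chrom", "pos", "ref", "alt", "vaf"])


def write_variants(variants: pd.DataFrame, path) -> None:
    variants.to_csv(path, sep="\t", index=False)


def read_manifest(path) -> pd.DataFrame:
    return _read(path, ["sample_id", "prep_type"])


def write_manifest(manifest: pd.DataFrame, path) -> None:
    manifest.to_csv(path, sep="\t", index=False)


def write_variants_vcf(variants: pd.DataFrame, path, sample_id: str = "TUMOR") -> None:
    """Export a somatic variant table as VCF with VAF in the AF INFO field."""
    import pysam

    header = pysam.VariantHeader()
    for chrom in pd.unique(variants["chrom"]):
        header.contigs.add(str(chrom))
    header.info.add("AF", number="A", type="Float", description="Variant allele fraction")
    header.info.add("GENE", number="1", type="String", description="Gene symbol")
    header.add_meta("source", value="cytoqc simulate")
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for rec in variants.sort_values(["chrom", "pos"]).to_dict("records"):
            row = vcf.new_record(
                contig=str(rec["chrom"]),
                start=int(rec["pos"]) - 1,
                stop=int(rec["pos"]),
                alleles=(str(rec["ref"]), str(rec["alt"])),
            )
            row.info["AF"] = float(rec["vaf"])
            if "gene" in rec:
                row.info["GENE"] = str(rec["gene"])
            vcf.write(row)
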