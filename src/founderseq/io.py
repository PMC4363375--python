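"""Readers and writers for the file formats the pipeline consumes.

Variant tables move either as sites-only VCF 4.2 (INFO keys ``DP``, ``VR``,
``USS``, ``CSQ``, ``GENE`` carrying the read evidence and annotation; one
file per sample) or as a flat 11-column TSV.  Regions come in as BED
(0-based half-open) and are converted to the 1-based inclusive convention
used internally.  Reference-panel allele counts are a TSV of
``panel, chrom, pos, ref, alt, alt_count, total_chromosomes``.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
import pysam
import yaml

from .filtering import ReadEvidence, RegionSet, VariantRecord, VariantKey

_CONTIG_LINES = "".join(
    f"##contig=<ID=chr{c}>\n" for c in [*range(1, 23), "X", "Y"]
)

_VCF_HEADER = f"""\
##fileformat=VCFv4.2
{_CONTIG_LINES}\
##INFO=<ID=DP,Number=1,Type=Integer,Description="Total read depth">
##INFO=<ID=VR,Number=1,Type=Integer,Description="Reads supporting the alternate allele">
##INFO=<ID=USS,Number=1,Type=Integer,Description="Unique alignment start sites among variant reads">
##INFO=<ID=CSQ,Number=1,Type=String,Description="Consequence class">
##INFO=<ID=GENE,Number=1,Type=String,Description="Gene symbol">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO
"""

VARIANT_TABLE_COLUMNS = [
    "sample_id",
    "chrom",
    "pos",
    "ref",
    "alt",
    "gene",
    "consequence",
    "known",
    "depth",
    "variant_reads",
    "unique_start_sites",
]


def write_sample_vcf(
    records: Sequence[VariantRecord], path: str | Path, sort: bool = True
) -> None:
    """Write one sample's variant records as a sites-only VCF."""
    recs = list(records)
    if sort:
        recs.sort(key=lambda r: (r.chrom, r.pos, r.ref, r.alt))
    with Path(path).open("w") as fh:
        fh.write(_VCF_HEADER)
        for r in recs:
            ev = r.evidence or ReadEvidence(0, 0, 0)
            info = (
                f"DP={ev.depth};VR={ev.variant_reads};USS={ev.unique_start_sites};"
                f"CSQ={r.consequence or '.'}"
            )
            if r.gene:
                info += f";GENE={r.gene}"
            fh.write(
                f"{r.chrom}\t{r.pos}\t.\t{r.ref}\t{r.alt}\t.\t.\t{info}\n"
            )


def read_sample_vcf(path: str | Path, sample_id: str) -> list[VariantRecord]:
    """Read a sites-only per-sample VCF written by :func:`write_sample_vcf`.

    Also accepts any VCF whose INFO carries DP/VR/USS/CSQ/GENE keys.
    """
    records: list[VariantRecord] = []
    with pysam.VariantFile(str(path)) as vf:
        for rec in vf:
            info = rec.info
            for alt in rec.alts or ():
                records.append(
                    VariantRecord(
                        sample_id=sample_id,
                        chrom=rec.chrom,
                        pos=rec.pos,
                        ref=rec.ref,
                        alt=alt,
                        gene=info.get("GENE"),
                        consequence=info.get("CSQ"),
                        evidence=ReadEvidence(
                            depth=int(info.get("DP", 0)),
                            variant_reads=int(info.get("VR", 0)),
                            unique_start_sites=int(info.get("USS", 0)),
                        ),
                    )
                )
    return records


def write_variant_table(records: Sequence[VariantRecord], path: str | Path) -> None:
    rows = [
        {
            "sample_id": r.sample_id,
            "chrom": r.chrom,
            "pos": r.pos,
            "ref": r.ref,
            "alt": r.alt,
            "gene": r.gene or ".",
            "consequence": r.consequence or ".",
            "known": int(r.known),
            "depth": r.evidence.depth if r.evidence else 0,
            "variant_reads": r.evidence.variant_reads if r.evidence else 0,
            "unique_start_sites": r.evidence.unique_start_sites if r.evidence else 0,
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=VARIANT_TABLE_COLUMNS).to_csv(path, sep="\t", index=False)


def read_variant_table(path: str | Path) -> list[VariantRecord]:
    """Read the documented 11-column TSV of per-sample variant records."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = set(VARIANT_TABLE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"variant table {path} lacks columns: {sorted(missing)}")
    records = []
    for row in df.itertuples(index=False):
        records.append(
            VariantRecord(
                sample_id=str(row.sample_id),
                chrom=str(row.chrom),
                pos=int(row.pos),
                ref=str(row.ref),
                alt=str(row.alt),
                gene=None if row.gene in (".", "") else str(row.gene),
                consequence=None if row.consequence in (".", "") else str(row.consequence),
                known=bool(row.known),
                evidence=ReadEvidence(
                    depth=int(row.depth),
                    variant_reads=int(row.variant_reads),
                    unique_start_sites=int(row.unique_start_sites),
                ),
            )
        )
    return records


def write_known_catalogue_vcf(keys: Iterable[VariantKey], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write(_VCF_HEADER)
        for chrom, pos, ref, alt in sorted(keys):
            fh.write(f"{chrom}\t{pos}\t.\t{ref}\t{alt}\t.\t.\t.\n")


def read_known_catalogue(path: str | Path) -> set[VariantKey]:
    """Known-variant site keys from a VCF (or the package's variant TSV)."""
    path = Path(path)
    keys: set[VariantKey] = set()
    if path.suffix.lower() in (".tsv", ".txt"):
        df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
        for row in df.itertuples(index=False):
            keys.add((str(row.chrom), int(row.pos), str(row.ref), str(row.alt)))
        return keys
    with pysam.VariantFile(str(path)) as vf:
        for rec in vf:
            for alt in rec.alts or ():
                keys.add((rec.chrom, rec.pos, rec.ref, alt))
    return keys


def write_bed(regions: RegionSet, path: str | Path) -> None:
    """Write regions as BED (converting 1-based inclusive to 0-based half-open)."""
    with Path(path).open("w") as fh:
        for chrom, start, end in regions.intervals:
            name = regions.label or "."
            fh.write(f"{chrom}\t{start - 1}\t{end}\t{name}\n")


def read_bed(path: str | Path, label: str = "") -> RegionSet:
    """Read a BED file into 1-based inclusive intervals."""
    intervals: list[tuple[str, int, int]] = []
    with Path(path).open() as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            intervals.append((chrom, start + 1, end))
    return RegionSet(intervals=intervals, label=label)


def read_panel_counts(path: str | Path) -> pd.DataFrame:
    """Reference-panel allele counts.

    Columns: panel, chrom, pos, ref, alt, alt_count, total_chromosomes.
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    required = {"panel", "chrom", "pos", "ref", "alt", "alt_count", "total_chromosomes"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"panel counts table {path} lacks columns: {sorted(missing)}")
    return df


def read_genotype_table(path: str | Path) -> pd.DataFrame:
    """Genotype matrix TSV: first column individual id, remaining columns
    variant names with allele counts 0/1/2 (blank for missing)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    return df


def load_yaml_config(path: str | Path) -> dict:
    with Path(path).open() as fh:
        return yaml.safe_load(fh) or {}
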