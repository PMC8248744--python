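"""Readers and writers for the pipeline's plain-text formats.

Conventions: site tables are 1-based inclusive (VCF-like); interval exports
(BED) are 0-based half-open.  All tables are tab-separated with a header
line.  ``read_x`` composed with ``write_x`` is the identity on the data
model.
"""

from __future__ import annotations

import hashlib
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from hapbsa.layout import GenomeLayout
from hapbsa.scan import WindowTrack

__all__ = [
    "write_layout", "read_layout",
    "write_sites", "read_sites",
    "write_counts", "read_counts",
    "write_bed", "read_bed",
    "write_gff3",
    "write_track", "read_track",
    "write_vcf", "read_vcf_sites",
    "sha256_of",
]


def write_layout(layout: GenomeLayout, path: str | Path) -> None:
    pd.DataFrame(layout.chromosomes, columns=["chrom", "length"]).to_csv(
        path, sep="\t", index=False
    )


def read_layout(path: str | Path) -> GenomeLayout:
    df = pd.read_csv(path, sep="\t")
    return GenomeLayout(tuple((str(c), int(l)) for c, l in zip(df["chrom"], df["length"])))


def write_sites(records: pd.DataFrame, path: str | Path) -> None:
    """Site table (chrom, pos 1-based, transmitted_allele, per-sample
    columns) as TSV."""
    records.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_sites(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", na_values=["NA"])
    for col in ("transmitted_allele", "excluded_reason"):
        if col in df.columns:
            df[col] = df[col].astype("string")
    required = {"chrom", "pos"}
    if not required.issubset(df.columns):
        raise ValueError(f"sites file {path} lacks columns {required - set(df.columns)}")
    return df


def write_counts(matrix: pd.DataFrame, path: str | Path) -> None:
    """Genes x samples count matrix; first column is the gene id."""
    matrix.to_csv(path, sep="\t", index_label="gene")


def read_counts(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="gene")


def write_bed(intervals: pd.DataFrame, path: str | Path) -> None:
    """Intervals (1-based inclusive ``start``/``end`` columns in the data
    model) exported as BED: 0-based half-open."""
    out = intervals.copy()
    out["bed_start"] = out["start"] - 1
    out["bed_end"] = out["end"]
    cols = ["chrom", "bed_start", "bed_end"] + [
        c for c in out.columns if c not in ("chrom", "start", "end", "bed_start", "bed_end")
    ]
    out[cols].to_csv(path, sep="\t", index=False, header=False)


def read_bed(path: str | Path, names: list[str] | None = None) -> pd.DataFrame:
    """Read BED back into the 1-based inclusive data model."""
    df = pd.read_csv(path, sep="\t", header=None)
    cols = ["chrom", "bed_start", "bed_end"] + (
        names if names is not None else [f"col{i}" for i in range(3, df.shape[1])]
    )
    df.columns = cols[: df.shape[1]]
    df["start"] = df["bed_start"] + 1
    df["end"] = df["bed_end"]
    return df.drop(columns=["bed_start", "bed_end"])


def write_gff3(annotation: pd.DataFrame, path: str | Path, source: str = "hapbsa") -> None:
    """Gene annotation as GFF3 (1-based inclusive, like the data model)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for _, row in annotation.iterrows():
            fh.write(
                f"{row['chrom']}\t{source}\tgene\t{row['start']}\t{row['end']}\t.\t+\t.\t"
                f"ID={row['gene']}\n"
            )


def write_track(track: WindowTrack, path: str | Path) -> None:
    """Window track as TSV (chrom, start, end 1-based inclusive, n_sites,
    value)."""
    track.to_frame().to_csv(path, sep="\t", index=False, na_rep="NA")


def read_track(path: str | Path) -> WindowTrack:
    df = pd.read_csv(path, sep="\t", na_values=["NA"])
    return WindowTrack(
        chrom=df["chrom"].to_numpy(dtype=object),
        start=df["start"].to_numpy(dtype=np.int64),
        end=df["end"].to_numpy(dtype=np.int64),
        n_sites=df["n_sites"].to_numpy(dtype=np.int64),
        value=df["value"].to_numpy(dtype=float),
    )


def write_vcf(
    records: pd.DataFrame,
    populations: list[str],
    layout: GenomeLayout,
    path: str | Path,
) -> None:
    """Minimal VCF of biallelic marker sites with per-pool allelic depths.

    ``records`` needs ``chrom``/``pos`` plus ``ref_<pop>``/``alt_<pop>``
    count columns; genotypes are left uncalled (pools, not individuals) and
    depths go into the AD FORMAT field.
    """
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for name, length in layout.chromosomes:
            fh.write(f"##contig=<ID={name},length={length}>\n")
        fh.write('##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(populations) + "\n")
        for _, row in records.iterrows():
            fields = [str(row["chrom"]), str(int(row["pos"])), ".", "A", "T", ".", "PASS", ".", "AD"]
            for pop in populations:
                fields.append(f"{int(row[f'ref_{pop}'])},{int(row[f'alt_{pop}'])}")
            fh.write("\t".join(fields) + "\n")


def read_vcf_sites(path: str | Path) -> pd.DataFrame:
    """Ingest biallelic SNP records from a VCF into the site data model.

    Uses cyvcf2 when importable, falling back to a plain-text parse of the
    same minimal subset.  Multi-allelic and indel records are skipped with a
    warning (the analysis is SNP-based).
    """
    try:
        from cyvcf2 import VCF  # noqa: PLC0415
    except ImportError:
        VCF = None
    rows = []
    skipped = 0
    if VCF is not None:
        vcf = VCF(str(path))
        pops = list(vcf.samples)
        for rec in vcf:
            if len(rec.ALT) != 1 or len(rec.REF) != 1 or len(rec.ALT[0]) != 1:
                skipped += 1
                continue
            ad = rec.format("AD")
            row = {"chrom": rec.CHROM, "pos": rec.POS}
            for j, pop in enumerate(pops):
                row[f"ref_{pop}"] = int(ad[j][0])
                row[f"alt_{pop}"] = int(ad[j][1])
            rows.append(row)
    else:
        pops = []
        with open(path) as fh:
            for line in fh:
                if line.startswith("##"):
                    continue
                parts = line.rstrip("\n").split("\t")
                if line.startswith("#CHROM"):
                    pops = parts[9:]
                    continue
                ref, alt = parts[3], parts[4]
                if "," in alt or len(ref) != 1 or len(alt) != 1:
                    skipped += 1
                    continue
                fmt = parts[8].split(":")
                ad_i = fmt.index("AD")
                row = {"chrom": parts[0], "pos": int(parts[1])}
                for pop, sample in zip(pops, parts[9:]):
                    ref_n, alt_n = sample.split(":")[ad_i].split(",")[:2]
                    row[f"ref_{pop}"] = int(ref_n)
                    row[f"alt_{pop}"] = int(alt_n)
                rows.append(row)
    if skipped:
        warnings.warn(f"skipped {skipped} non-biallelic-SNP VCF records", stacklevel=2)
    return pd.DataFrame(rows)


def sha256_of(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()
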