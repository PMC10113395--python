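"""Readers and writers for the pipeline's on-disk formats.

All tabular formats are plain TSV; sequences are FASTA (via Biopython);
genomic intervals are 0-based half-open BED.  The peptide report schema
follows a DIA software export: one row per peptidoform with columns
``peptide_sequence``, ``modifications`` (semicolon-separated
``Name@position``, 1-based; empty for the unmodified form), ``protein_id``,
then one intensity column per sample.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_peptide_report",
    "write_peptide_report",
    "read_design",
    "parse_modifications",
    "format_modifications",
    "read_fragments_bed",
    "write_fragments_bed",
    "read_loci_bed",
    "write_loci_bed",
    "read_gwas_table",
    "read_counts_tsv",
    "write_counts_tsv",
    "read_truth",
    "write_truth",
]

REPORT_FIXED_COLUMNS = ["peptide_sequence", "modifications", "protein_id"]


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into an ordered ``{id: sequence}`` mapping."""
    records = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        records[rec.id] = str(rec.seq).upper()
    return records


def write_fasta(sequences: dict[str, str], path: str | Path, width: int = 60) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    with open(path, "w") as handle:
        writer = SeqIO.FastaIO.FastaWriter(handle, wrap=width)
        writer.write_file(records)


def parse_modifications(spec: str) -> list[tuple[str, int]]:
    """Parse ``"Oxidation@3;Acetyl@0"`` into ``[("Oxidation", 3), ("Acetyl", 0)]``."""
    if not spec or (isinstance(spec, float) and pd.isna(spec)):
        return []
    mods = []
    for token in str(spec).split(";"):
        token = token.strip()
        if not token:
            continue
        name, _, pos = token.partition("@")
        mods.append((name, int(pos)))
    return mods


def format_modifications(mods: Iterable[tuple[str, int]]) -> str:
    return ";".join(f"{name}@{pos}" for name, pos in mods)


def read_peptide_report(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"modifications": str})
    missing = [c for c in REPORT_FIXED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"peptide report missing columns: {missing}")
    df["modifications"] = df["modifications"].fillna("")
    return df


def write_peptide_report(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_design(path: str | Path) -> pd.DataFrame:
    """Read a sample→group design TSV with columns ``sample`` and ``group``."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("sample", "group"):
        if col not in df.columns:
            raise ValueError(f"design table missing column {col!r}")
    return df


def read_fragments_bed(path: str | Path) -> pd.DataFrame:
    """Read fragments as BED3 + sample name (4th column)."""
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        names=["chrom", "start", "end", "sample"],
        dtype={"chrom": str, "start": int, "end": int, "sample": str},
    )
    if (df["end"] <= df["start"]).any():
        bad = df.index[df["end"] <= df["start"]][0]
        raise ValueError(f"fragment with end <= start at line {bad + 1}")
    return df


def write_fragments_bed(df: pd.DataFrame, path: str | Path) -> None:
    df[["chrom", "start", "end", "sample"]].to_csv(
        path, sep="\t", header=False, index=False
    )


def read_loci_bed(path: str | Path) -> pd.DataFrame:
    """Read tRNA gene coordinates as BED6 (name in column 4, strand in 6)."""
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        names=["chrom", "start", "end", "locus_id", "score", "strand"],
        dtype={"chrom": str, "start": int, "end": int, "locus_id": str},
    )
    return df


def write_loci_bed(df: pd.DataFrame, path: str | Path) -> None:
    out = df.copy()
    if "score" not in out.columns:
        out["score"] = 0
    if "strand" not in out.columns:
        out["strand"] = "+"
    out[["chrom", "start", "end", "locus_id", "score", "strand"]].to_csv(
        path, sep="\t", header=False, index=False
    )


def read_gwas_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "category": str})
    for col in ("chrom", "pos", "pvalue", "category"):
        if col not in df.columns:
            raise ValueError(f"GWAS table missing column {col!r}")
    return df


def read_counts_tsv(path: str | Path) -> pd.DataFrame:
    """Read long-format footprint 5'-end counts:
    transcript_id, position (0-based nt), sample, count."""
    return pd.read_csv(
        path,
        sep="\t",
        dtype={"transcript_id": str, "position": int, "sample": str, "count": int},
    )


def write_counts_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_truth(path: str | Path) -> dict:
    with open(path) as fh:
        return json.load(fh)


def write_truth(truth: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(truth, fh, indent=2, sort_keys=True)
        fh.write("\n")
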