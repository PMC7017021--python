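"""Readers and writers for the plain-text formats used by the pipeline:
FASTA genomes, GFF3 annotations, BED interval tracks and TSV site tables."""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import DataError

SITE_TABLE_COLUMNS = [
    "chrom",
    "pos",
    "site_class",
    "ancestral",
    "derived",
    "derived_count",
    "n_haplotypes",
    "context3",
    "gene_id",
    "codon",
    "strand",
]

_SITE_DTYPES = {
    "chrom": str,
    "pos": "int64",
    "site_class": str,
    "ancestral": str,
    "derived": str,
    "derived_count": "int64",
    "n_haplotypes": "int64",
    "context3": str,
    "gene_id": str,
    "codon": str,
    "strand": str,
}


def read_genome(path) -> dict:
    """FASTA -> {name: uppercase sequence string}."""
    genome = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}
    if not genome:
        raise DataError(f"no sequences found in {path}")
    return genome


def write_genome(genome: dict, path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in genome.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def write_gff3(features, path) -> None:
    """Write feature rows (dicts with chrom, source, type, start, end, score,
    strand, phase, attributes) as GFF3."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for f in features:
            fh.write(
                "\t".join(
                    str(f.get(k, "."))
                    for k in (
                        "chrom",
                        "source",
                        "type",
                        "start",
                        "end",
                        "score",
                        "strand",
                        "phase",
                        "attributes",
                    )
                )
                + "\n"
            )


def read_bed(path) -> pd.DataFrame:
    """BED (0-based half-open) -> DataFrame(chrom, start, end[, name])."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise DataError(f"{path}: malformed BED line {lineno}: {line!r}")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise DataError(
                    f"{path}: non-integer coordinates on BED line {lineno}"
                ) from exc
            if end < start:
                raise DataError(f"{path}: end < start on BED line {lineno}")
            rows.append(
                {
                    "chrom": parts[0],
                    "start": start,
                    "end": end,
                    "name": parts[3] if len(parts) > 3 else ".",
                }
            )
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name"])


def write_bed(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", header=False, index=False)


def read_site_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=_SITE_DTYPES)
    missing = [c for c in SITE_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise DataError(f"{path}: site table missing columns {missing}")
    return df


def write_site_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def read_json(path):
    return json.loads(Path(path).read_text())
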