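"""Readers and writers for the package's on-disk formats.

Conventions: internal coordinates are 0-based half-open; GFF3 on disk is
1-based inclusive; site tables carry 1-based positions.  All tabular files
are tab-separated with a single header line and a fixed float format so
that identically configured runs are byte-identical.
"""
from __future__ import annotations

import json
from pathlib import Path

import gffutils
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import InputError

FLOAT_FORMAT = "%.6g"


# ---------------------------------------------------------------------------
# sequence + annotation

def write_fasta(sequences: dict[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_gff3(genes: pd.DataFrame, path: str | Path, source: str = "graftomics") -> None:
    """Write gene models (columns gene_id, chrom, start, end, strand;
    start/end 0-based half-open) as GFF3 gene features."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for row in genes.itertuples(index=False):
            attrs = f"ID={row.gene_id};Name={row.gene_id}"
            fh.write(
                f"{row.chrom}\t{source}\tgene\t{row.start + 1}\t{row.end}\t.\t{row.strand}\t.\t{attrs}\n"
            )


def read_gff3(path: str | Path) -> pd.DataFrame:
    """Read gene features back into the internal 0-based half-open frame."""
    db = gffutils.create_db(str(path), ":memory:", force=True, keep_order=True)
    rows = []
    for feat in db.features_of_type("gene", order_by="start"):
        rows.append(
            {
                "gene_id": feat.id,
                "chrom": feat.seqid,
                "start": feat.start - 1,
                "end": feat.end,
                "strand": feat.strand,
            }
        )
    if not rows:
        raise InputError(f"{path}: no gene features found")
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# tables

def write_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)


def read_tsv(path: str | Path, **kwargs) -> pd.DataFrame:
    p = Path(path)
    if not p.exists():
        raise InputError(f"missing input table: {p}")
    return pd.read_csv(p, sep="\t", **kwargs)


def write_manifest(manifest: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_manifest(path: str | Path) -> dict:
    with open(path) as fh:
        return json.load(fh)
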