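"""Readers and writers for the flat-file formats the pipeline exchanges.

GFF3 gene tables (1-based inclusive, ``gene`` features, ``ID=`` attributes,
NLRs flagged with ``Note=NLR``), FASTA protein sets, HMMER3-style per-domain
tables, and labelled TSV distance matrices.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .alignment_free import DistanceMatrix
from .cluster_genomics import GENE_COLUMNS


def write_gff3(genes: pd.DataFrame, path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for row in genes.itertuples(index=False):
            attrs = f"ID={row.gene_id}"
            if row.is_nlr:
                attrs += ";Note=NLR"
            fh.write(
                f"{row.contig}\tnlrscape\tgene\t{row.start}\t{row.end}\t.\t{row.strand}\t.\t{attrs}\n"
            )


def read_gff3(path) -> pd.DataFrame:
    """Read a gene-feature GFF3 back into a gene table.

    Only ``gene`` features are kept; a gene is flagged NLR when its
    attributes carry ``Note=NLR``.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 9:
                raise ValueError(f"{path}: expected 9 GFF3 columns at line {lineno}")
            contig, _, ftype, start, end, _, strand, _, attrs = parts
            if ftype != "gene":
                continue
            attr_map = dict(
                kv.split("=", 1) for kv in attrs.split(";") if "=" in kv
            )
            if "ID" not in attr_map:
                raise ValueError(f"{path}: gene without ID at line {lineno}")
            rows.append(
                (
                    attr_map["ID"],
                    contig,
                    int(start),
                    int(end),
                    strand,
                    attr_map.get("Note") == "NLR",
                )
            )
    return pd.DataFrame(rows, columns=GENE_COLUMNS)


def write_fasta(seqs: dict[str, str], path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, path, "fasta")


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(path, "fasta")}


def write_domtblout(hits: pd.DataFrame, path) -> None:
    """Write a hit table in the HMMER3 per-domain (domtblout) column layout.

    Columns the pipeline does not model (accessions, biases, hmm/ali
    coordinates, acc) are filled with placeholders; envelope coordinates
    carry the region and the i-E-value column the E-value.
    """
    with open(path, "w") as fh:
        fh.write("# synthetic domain hits (HMMER3 domtblout dialect)\n")
        for row in hits.itertuples(index=False):
            cols = [
                row.gene_id, "-", "0", row.profile, "-", "0",
                f"{row.evalue:.2g}", f"{row.score:.1f}", "0.0",
                "1", "1",
                f"{row.evalue:.2g}", f"{row.evalue:.2g}",
                f"{row.score:.1f}", "0.0",
                "1", "1",
                str(row.aa_start), str(row.aa_end),
                str(row.aa_start), str(row.aa_end),
                "0.99", "-",
            ]
            fh.write(" ".join(cols) + "\n")


def write_distance_matrix(dm: DistanceMatrix, path) -> None:
    pd.DataFrame(dm.values, index=list(dm.labels), columns=list(dm.labels)).to_csv(
        path, sep="\t"
    )


def read_distance_matrix(path) -> DistanceMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return DistanceMatrix(tuple(df.index), np.asarray(df.values, dtype=float))
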