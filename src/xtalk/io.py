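"""Readers and writers for the plain-text formats the pipeline exchanges.

Coordinates are 0-based half-open (BED convention) everywhere in memory;
conversion to GFF3's 1-based closed coordinates happens at the writer/reader
boundary.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


def write_fasta(sequences: Mapping[str, str], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_gff3(features: pd.DataFrame, path: str | Path, source: str = "xtalk") -> None:
    """Write gene/exon features (seq_id, start, end, gene_id[, type]) as GFF3.

    Half-open input coordinates become GFF3's 1-based closed spans.
    """
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for row in features.itertuples(index=False):
            ftype = getattr(row, "type", "gene")
            fh.write(
                f"{row.seq_id}\t{source}\t{ftype}\t{int(row.start) + 1}\t"
                f"{int(row.end)}\t.\t+\t.\tID={row.gene_id}\n"
            )


def read_gff3(path: str | Path) -> pd.DataFrame:
    """Read GFF3 back into half-open coordinates (seq_id, start, end, gene_id, type)."""
    rows = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            attrs = dict(
                kv.split("=", 1) for kv in f[8].split(";") if "=" in kv
            )
            rows.append(
                {
                    "seq_id": f[0],
                    "start": int(f[3]) - 1,
                    "end": int(f[4]),
                    "gene_id": attrs.get("ID", "."),
                    "type": f[2],
                }
            )
    return pd.DataFrame(rows, columns=["seq_id", "start", "end", "gene_id", "type"])


def write_bed(intervals: pd.DataFrame, path: str | Path) -> None:
    """Write BED6; the ``name`` column carries the feature family or label."""
    with open(path, "w") as fh:
        for row in intervals.itertuples(index=False):
            name = getattr(row, "family", getattr(row, "name", "."))
            score = getattr(row, "score", 0)
            strand = getattr(row, "strand", "+")
            fh.write(
                f"{row.seq_id}\t{int(row.start)}\t{int(row.end)}\t{name}\t{score}\t{strand}\n"
            )


def read_bed(path: str | Path) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            f = line.rstrip("\n").split("\t")
            row = {"seq_id": f[0], "start": int(f[1]), "end": int(f[2])}
            if len(f) > 3:
                row["family"] = f[3]
            rows.append(row)
    return pd.DataFrame(rows)


def write_counts(counts: pd.DataFrame, path: str | Path) -> None:
    counts.to_csv(path, sep="\t", index_label="gene_id")


def read_counts(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="gene_id")


def write_reads_bed(reads: Mapping[str, "object"], seq_id: str, path: str | Path) -> None:
    """Write per-sample read intervals as a BED-like table (chrom, start, end, sample)."""
    with open(path, "w") as fh:
        for sample, intervals in reads.items():
            for start, end in intervals:
                fh.write(f"{seq_id}\t{int(start)}\t{int(end)}\t{sample}\n")


def read_reads_bed(path: str | Path) -> dict[str, list[tuple[int, int]]]:
    out: dict[str, list[tuple[int, int]]] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            _, start, end, sample = line.rstrip("\n").split("\t")[:4]
            out.setdefault(sample, []).append((int(start), int(end)))
    return out


def read_edge_lists(path: str | Path) -> dict[str, list[tuple[str, str]]]:
    """Read pathway edge lists from a TSV (node_a, node_b, source_pathway)."""
    pathways: dict[str, list[tuple[str, str]]] = {}
    df = pd.read_csv(path, sep="\t", header=None, names=["a", "b", "pathway"])
    for row in df.itertuples(index=False):
        pathways.setdefault(str(row.pathway), []).append((str(row.a), str(row.b)))
    return pathways


def write_calls(calls: Sequence, path: str | Path) -> None:
    """Write TriadCall-like records as TSV (gene_id, code, category)."""
    pd.DataFrame(
        [{"gene_id": c.gene_id, "code": c.code, "category": c.category} for c in calls]
    ).to_csv(path, sep="\t", index=False)
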