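"""FASTA/TSV readers and writers with deterministic formatting."""

from __future__ import annotations

import pandas as pd

FLOAT_FORMAT = "%.10g"


def read_fasta(path) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: dict[str, str], path, width: int = 70):
    with open(path, "w") as handle:
        for name, seq in sequences.items():
            handle.write(f">{name}\n")
            for i in range(0, len(seq), width):
                handle.write(seq[i:i + width] + "\n")


def write_tsv(df: pd.DataFrame, path, index=True):
    df.to_csv(path, sep="\t", index=index, float_format=FLOAT_FORMAT)


def read_counts_tsv(path):
    """counts.tsv with transcript_id index, optional gene_id/length columns.

    Returns (counts, lengths or None, gene_map or None).
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    gene_map = df.pop("gene_id") if "gene_id" in df.columns else None
    lengths = df.pop("length") if "length" in df.columns else None
    return df, lengths, gene_map
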