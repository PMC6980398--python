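"""Readers and writers for the plain-text formats the pipeline consumes:
counts TSV / MatrixMarket, sample metadata TSV, GMT gene-set collections,
two-column ortholog maps, FASTA promoters, BED TSS records, JASPAR- and
HOMER-style motif matrices, and long peptide CSVs."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO, motifs as bio_motifs

from .enrichment import PWM

__all__ = [
    "read_counts_tsv", "write_counts_tsv", "read_counts_mtx",
    "read_metadata", "write_metadata",
    "read_gmt", "write_gmt",
    "read_ortholog_map",
    "read_fasta", "write_fasta",
    "read_bed",
    "read_jaspar_motifs", "read_homer_motifs",
    "read_peptide_csv", "write_peptide_csv",
]


def read_counts_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df


def write_counts_tsv(counts: pd.DataFrame, path: str | Path) -> None:
    counts.to_csv(path, sep="\t")


def read_counts_mtx(mtx: str | Path, genes: str | Path,
                    samples: str | Path) -> pd.DataFrame:
    from scipy.io import mmread
    m = mmread(str(mtx)).toarray()
    gene_ids = pd.read_csv(genes, header=None)[0]
    sample_ids = pd.read_csv(samples, header=None)[0]
    return pd.DataFrame(m, index=gene_ids, columns=sample_ids)


def read_metadata(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_metadata(meta: pd.DataFrame, path: str | Path) -> None:
    meta.to_csv(path, sep="\t")


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """GMT: one set per line — name, description, member ids (tab-sep)."""
    sets: dict[str, list[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"malformed GMT line: {line[:60]!r}")
        name, members = parts[0], [g for g in parts[2:] if g]
        if not members:
            raise ValueError(f"gene set {name!r} is empty")
        if name in sets:
            raise ValueError(f"duplicate gene set name {name!r}")
        sets[name] = list(dict.fromkeys(members))
    return sets


def write_gmt(sets: dict[str, list[str]], path: str | Path,
              description: str = "na") -> None:
    with open(path, "w") as fh:
        for name, members in sets.items():
            fh.write("\t".join([name, description, *members]) + "\n")


def read_ortholog_map(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 2:
        raise ValueError("ortholog map needs two columns of gene ids")
    return df.iloc[:, :2]


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper()
            for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: dict[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def read_bed(path: str | Path) -> pd.DataFrame:
    """Six-column BED (chrom, start, end, name, score, strand)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if df.shape[1] < 6:
        raise ValueError("BED file must have 6 columns including strand")
    df = df.iloc[:, :6]
    df.columns = ["chrom", "start", "end", "name", "score", "strand"]
    return df


def read_jaspar_motifs(path: str | Path, threshold: float = 0.90) -> list[PWM]:
    """JASPAR-format PFMs, normalised to probability matrices."""
    out = []
    with open(path) as fh:
        for m in bio_motifs.parse(fh, "jaspar"):
            counts = np.array([m.counts[b] for b in "ACGT"], dtype=float).T
            probs = counts / counts.sum(axis=1, keepdims=True)
            out.append(PWM(m.matrix_id or m.name, probs, threshold))
    return out


def read_homer_motifs(path: str | Path, threshold: float = 0.90) -> list[PWM]:
    """HOMER .motif: '>consensus<TAB>name<TAB>log-odds-threshold' headers
    followed by per-position A C G T probability rows."""
    out = []
    name, rows = None, []
    def flush():
        if name is not None:
            mat = np.array(rows, dtype=float)
            mat = mat / mat.sum(axis=1, keepdims=True)
            out.append(PWM(name, mat, threshold))
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        if line.startswith(">"):
            flush()
            fields = line[1:].split("\t")
            name = fields[1] if len(fields) > 1 else fields[0]
            rows = []
        else:
            rows.append([float(v) for v in line.split()])
    flush()
    return out


def read_peptide_csv(path: str | Path) -> pd.DataFrame:
    """Long peptide CSV; empty intensity fields mean censored (NaN)."""
    df = pd.read_csv(path)
    df["intensity"] = pd.to_numeric(df["intensity"], errors="coerce")
    return df


def write_peptide_csv(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, index=False, na_rep="")
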