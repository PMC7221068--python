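"""Readers and writers for the pipeline's plain-text interchange formats.

FASTA and FASTQ go through Biopython; tabular formats (GTF, ortholog TSV,
count tables, narrowPeak, bedGraph) are pandas-backed. Count-table TSVs carry
the per-sample metadata as a ``#meta`` header block so a single file round-trips
a :class:`~hybridshock.syndata.CountTable`.
"""

from __future__ import annotations

import io as _io
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

GTF_COLUMNS = [
    "seqname", "source", "feature", "start", "end",
    "score", "strand", "frame", "attribute",
]


# ---------------------------------------------------------------- sequences
def write_fasta(sequences: dict[str, str], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fastq(reads: pd.DataFrame, path: str | Path) -> None:
    """Write reads with columns ``name, seq`` (constant dummy quality)."""
    with open(path, "w") as fh:
        for row in reads.itertuples(index=False):
            fh.write(f"@{row.name}\n{row.seq}\n+\n{'I' * len(row.seq)}\n")


def read_fastq(path: str | Path) -> pd.DataFrame:
    names, seqs = [], []
    for rec in SeqIO.parse(str(path), "fastq"):
        names.append(rec.description or rec.id)
        seqs.append(str(rec.seq))
    return pd.DataFrame({"name": names, "seq": seqs})


# -------------------------------------------------------------- annotations
def write_gtf(annotations: pd.DataFrame, path: str | Path,
              source: str = "hybridshock") -> None:
    """Write gene annotations (1-based inclusive ``start``/``end``) as GTF."""
    rows = []
    for row in annotations.itertuples(index=False):
        attr = f'gene_id "{row.gene_id}";'
        rows.append((row.chrom, source, "gene", int(row.start), int(row.end),
                     ".", row.strand, ".", attr))
    pd.DataFrame(rows, columns=GTF_COLUMNS).to_csv(
        path, sep="\t", header=False, index=False, quoting=3)


def read_gtf(path: str | Path, feature: str = "gene") -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, names=GTF_COLUMNS, comment="#")
    df = df[df["feature"] == feature].copy()
    df["gene_id"] = df["attribute"].str.extract(r'gene_id "([^"]+)"')
    return df[["gene_id", "seqname", "start", "end", "strand"]].rename(
        columns={"seqname": "chrom"}).reset_index(drop=True)


def write_ortholog_map(orthologs: pd.DataFrame, path: str | Path) -> None:
    orthologs.to_csv(path, sep="\t", index=False)


def read_ortholog_map(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


# ------------------------------------------------------------- count tables
def write_count_table(table, path: str | Path) -> None:
    """Serialize a CountTable: ``#meta`` lines, then the counts matrix.

    Gene lengths are stored as a parallel ``#lengths`` block only when they
    vary; otherwise a single ``#gene_length_default`` line is emitted.
    """
    buf = _io.StringIO()
    meta = table.sample_meta
    for col in meta.columns:
        vals = "\t".join(str(v) for v in meta[col])
        buf.write(f"#meta\t{col}\t{vals}\n")
    counts = table.counts
    buf.write("gene\t" + "\t".join(counts.columns) + "\n")
    counts.to_csv(buf, sep="\t", header=False)
    if table.gene_lengths is not None:
        buf.write("#lengths\n")
        table.gene_lengths.to_csv(buf, sep="\t", header=False)
    Path(path).write_text(buf.getvalue())


def read_count_table(path: str | Path):
    from hybridshock.syndata import CountTable  # local import: avoid cycle

    meta_rows: dict[str, list[str]] = {}
    body: list[str] = []
    lengths: list[str] = []
    in_lengths = False
    for line in Path(path).read_text().splitlines():
        if line.startswith("#meta\t"):
            _, col, vals = line.split("\t", 2)
            meta_rows[col] = vals.split("\t")
        elif line.startswith("#lengths"):
            in_lengths = True
        elif in_lengths:
            lengths.append(line)
        else:
            body.append(line)
    counts = pd.read_csv(_io.StringIO("\n".join(body)), sep="\t", index_col=0)
    meta = pd.DataFrame(meta_rows)
    meta.index = pd.Index(counts.columns, name="sample")
    for col in ("replicate",):
        if col in meta:
            meta[col] = meta[col].astype(int)
    gl = None
    if lengths:
        gl = pd.read_csv(_io.StringIO("\n".join(lengths)), sep="\t",
                         header=None, index_col=0)
        gl.columns = counts.columns
        gl.index.name = counts.index.name
    return CountTable(counts=counts, sample_meta=meta, gene_lengths=gl)


# ------------------------------------------------------------------- tracks
def write_bedgraph(coverage: pd.DataFrame, path: str | Path) -> None:
    coverage[["chrom", "start", "end", "value"]].to_csv(
        path, sep="\t", header=False, index=False)


def read_bedgraph(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", header=None,
                       names=["chrom", "start", "end", "value"], comment="#")


def write_bed(df: pd.DataFrame, path: str | Path,
              columns: tuple[str, ...] = ("chrom", "start", "end", "name")) -> None:
    df[list(columns)].to_csv(path, sep="\t", header=False, index=False)
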