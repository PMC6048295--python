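"""Readers and writers for the external formats the pipeline touches.

External conventions: FASTA for sequences, GFF3 (1-based inclusive
coordinates) for gene models, TSV for matrices and tables, newick for trees.
Internally every coordinate is 0-based half-open; the conversion happens
here, at the I/O boundary, and nowhere else.
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass, field, replace

import dendropy
import gffutils
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord


class FileFormatError(ValueError):
    """Raised when an input file violates its format contract."""


AA_ONLY = set("EFILPQZ*")  # residues that cannot occur in a nucleotide string


@dataclass(frozen=True)
class SequenceRecord:
    """A single FASTA record (nucleotide or amino acid, uppercase)."""

    id: str
    sequence: str
    description: str = ""

    def __post_init__(self):
        if not self.id:
            raise ValueError("sequence record id must be non-empty")
        if not self.sequence:
            raise ValueError(f"sequence for {self.id!r} is empty")

    def __len__(self):
        return len(self.sequence)


def _is_nucleotide(seq: str) -> bool:
    return not (set(seq) & AA_ONLY) and set(seq) <= set("ACGTUNRYSWKMBDHV-")


def read_fasta(path, alphabet: str = "auto") -> list[SequenceRecord]:
    """Read a FASTA file into SequenceRecords.

    Sequences are uppercased; in nucleotide records ``U`` is mapped to ``T``
    (other ambiguity codes are preserved).  ``alphabet`` may be ``"nt"``,
    ``"aa"`` or ``"auto"`` (guess per record).

    Raises FileFormatError for an empty file or a duplicated id.
    """
    records = []
    seen = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FileFormatError(f"duplicate sequence id {rec.id!r} in {path}")
        seen.add(rec.id)
        seq = str(rec.seq).upper()
        is_nt = alphabet == "nt" or (alphabet == "auto" and _is_nucleotide(seq))
        if is_nt:
            seq = seq.replace("U", "T")
        records.append(SequenceRecord(rec.id, seq, rec.description[len(rec.id):].strip()))
    if not records:
        raise FileFormatError(f"no FASTA records in {path}")
    return records


def write_fasta(records, path, width: int = 60) -> None:
    bio = [
        _BioSeqRecord(Seq(r.sequence), id=r.id, description=r.description)
        for r in records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(bio)


# ---------------------------------------------------------------------------
# Gene models
# ---------------------------------------------------------------------------

@dataclass
class GeneModel:
    """One mRNA: exon and CDS intervals in 0-based half-open *genomic*
    coordinates, ordered 5'->3' in transcription order (so on the minus
    strand intervals run from high to low genomic position)."""

    gene_id: str
    seq_id: str
    strand: str
    exons: list[tuple[int, int]]
    cds: list[tuple[int, int]]
    complete: bool = True

    def __post_init__(self):
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r} for {self.gene_id}")
        for s, e in self.exons + self.cds:
            if e <= s:
                raise ValueError(f"empty interval ({s},{e}) in {self.gene_id}")
        genomic = sorted(self.exons)
        for (s1, e1), (s2, e2) in zip(genomic, genomic[1:]):
            if s2 < e1:
                raise ValueError(f"overlapping exons in {self.gene_id}")

    @property
    def cds_length(self) -> int:
        return sum(e - s for s, e in self.cds)

    @property
    def n_introns(self) -> int:
        return len(self.exons) - 1


def _txn_order(intervals, strand):
    return sorted(intervals, reverse=(strand == "-"))


def read_gff3(path) -> list[GeneModel]:
    """Read gene models from GFF3 (one model per mRNA).

    External coordinates are 1-based inclusive per the GFF3 standard and are
    converted to internal 0-based half-open.  A CDS segment outside the exon
    union is an error; a model whose total CDS length is not divisible by 3
    is flagged incomplete with a warning.
    """
    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", force=True
    )
    models = []
    for mrna in db.features_of_type("mRNA", order_by="start"):
        exons, cds = [], []
        for feat in db.children(mrna, featuretype="exon"):
            exons.append((feat.start - 1, feat.end))
        for feat in db.children(mrna, featuretype="CDS"):
            cds.append((feat.start - 1, feat.end))
        if not exons:
            exons = cds[:]
        for s, e in cds:
            if not any(es <= s and e <= ee for es, ee in exons):
                raise FileFormatError(
                    f"CDS segment [{s},{e}) of {mrna.id} extends outside exons"
                )
        strand = mrna.strand
        model = GeneModel(
            gene_id=mrna.id,
            seq_id=mrna.seqid,
            strand=strand,
            exons=_txn_order(exons, strand),
            cds=_txn_order(cds, strand),
        )
        if model.cds_length % 3 != 0:
            warnings.warn(
                f"CDS length of {mrna.id} not divisible by 3; model flagged incomplete"
            )
            model.complete = False
        models.append(model)
    return models


def write_gff3(models, path) -> None:
    """Write gene models back to GFF3 (gene + mRNA + exon + CDS rows)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for m in models:
            lo = min(s for s, _ in m.exons)
            hi = max(e for _, e in m.exons)
            base = f"{m.seq_id}\tmybkit\t"
            attr_gene = f"ID=gene:{m.gene_id}"
            fh.write(f"{base}gene\t{lo + 1}\t{hi}\t.\t{m.strand}\t.\t{attr_gene}\n")
            fh.write(
                f"{base}mRNA\t{lo + 1}\t{hi}\t.\t{m.strand}\t.\t"
                f"ID={m.gene_id};Parent=gene:{m.gene_id}\n"
            )
            for s, e in sorted(m.exons):
                fh.write(
                    f"{base}exon\t{s + 1}\t{e}\t.\t{m.strand}\t.\tParent={m.gene_id}\n"
                )
            for s, e in sorted(m.cds):
                fh.write(
                    f"{base}CDS\t{s + 1}\t{e}\t.\t{m.strand}\t0\tParent={m.gene_id}\n"
                )


# ---------------------------------------------------------------------------
# Matrices and Ct tables
# ---------------------------------------------------------------------------

@dataclass
class ExpressionMatrix:
    """Dense gene x sample expression table of non-negative reals."""

    values: pd.DataFrame  # index = gene ids, columns = sample ids
    units: str = "RPKM"  # "RPKM" or "counts"

    def __post_init__(self):
        df = self.values
        if df.shape[0] == 0 or df.shape[1] == 0:
            raise ValueError("expression matrix must have >=1 gene and sample")
        if df.isna().any().any():
            raise ValueError("expression matrix contains missing cells")
        if (df.values < 0).any():
            raise ValueError("expression values must be non-negative")
        if df.index.duplicated().any() or df.columns.duplicated().any():
            raise ValueError("duplicate gene or sample ids")

    @property
    def gene_ids(self):
        return list(self.values.index)

    @property
    def sample_ids(self):
        return list(self.values.columns)


def read_matrix(path, units: str = "RPKM") -> ExpressionMatrix:
    """Read a TSV matrix: header row = samples, first column = gene ids."""
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
    except pd.errors.ParserError as exc:
        raise FileFormatError(f"ragged or malformed matrix {path}: {exc}") from exc
    non_numeric = df.columns[
        [not pd.api.types.is_numeric_dtype(df[c]) for c in df.columns]
    ]
    if len(non_numeric):
        col = non_numeric[0]
        bad = df[col][pd.to_numeric(df[col], errors="coerce").isna()]
        row = bad.index[0] if len(bad) else "?"
        raise FileFormatError(
            f"non-numeric cell in {path} at row {row!r}, column {col!r}"
        )
    try:
        return ExpressionMatrix(df.astype(float), units=units)
    except ValueError as exc:
        raise FileFormatError(f"{path}: {exc}") from exc


def write_matrix(matrix: ExpressionMatrix, path) -> None:
    matrix.values.to_csv(path, sep="\t", index_label="gene_id")


CT_COLUMNS = ["sample_id", "gene_id", "replicate", "ct"]


def read_ct_table(path, reference_gene: str | None = None) -> pd.DataFrame:
    """Read a long-form qPCR Ct table (sample_id, gene_id, replicate, ct)."""
    df = pd.read_csv(path, sep="\t")
    missing = set(CT_COLUMNS) - set(df.columns)
    if missing:
        raise FileFormatError(f"Ct table {path} lacks columns {sorted(missing)}")
    if df["ct"].isna().any():
        raise FileFormatError(f"Ct table {path} contains missing Ct values")
    if reference_gene is not None:
        for sample, grp in df.groupby("sample_id"):
            if reference_gene not in set(grp["gene_id"]):
                raise FileFormatError(
                    f"reference gene {reference_gene!r} missing from sample {sample!r}"
                )
    return df[CT_COLUMNS].copy()


def write_ct_table(df: pd.DataFrame, path) -> None:
    df[CT_COLUMNS].to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Trees and edge lists
# ---------------------------------------------------------------------------

def write_newick(tree: dendropy.Tree, path) -> None:
    """Write a tree with bootstrap supports stored as internal-node labels."""
    with open(path, "w") as fh:
        fh.write(
            tree.as_string(
                schema="newick",
                suppress_rooting=True,
                unquoted_underscores=True,
            )
        )


def read_newick(path) -> dendropy.Tree:
    return dendropy.Tree.get(path=str(path), schema="newick")


def write_edge_list(edges, path) -> None:
    """Write (gene_i, gene_j, pcc) rows to TSV."""
    pd.DataFrame(edges, columns=["gene_i", "gene_j", "pcc"]).to_csv(
        path, sep="\t", index=False
    )


def read_edge_list(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if list(df.columns) != ["gene_i", "gene_j", "pcc"]:
        raise FileFormatError(f"bad edge list header in {path}")
    return df


def sha256_of(path) -> str:
    import hashlib

    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()
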