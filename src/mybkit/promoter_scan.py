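"""Cis-element scanning of fixed-length upstream promoter windows.

Elements are IUPAC degenerate nucleotide patterns supplied as a user table;
a small illustrative table of common hormone- and stress-responsive elements
(ABRE, MBS, LTR, TGACG-motif and friends) ships with the package.  Windows
are the 1500 bp 5' of the transcription start site in transcription
orientation; hits are reported on both strands, overlapping and nested hits
all included (counts are therefore upper bounds).
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass
from importlib import resources

import pandas as pd

from .io_formats import GeneModel, SequenceRecord

UPSTREAM_LENGTH = 1500

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class CisElement:
    name: str
    iupac_pattern: str
    category: str = ""

    def __post_init__(self):
        if not self.iupac_pattern:
            raise ValueError("empty IUPAC pattern")
        bad = set(self.iupac_pattern.upper()) - set(IUPAC)
        if bad:
            raise ValueError(f"invalid IUPAC codes {sorted(bad)} in {self.name}")


@dataclass(frozen=True)
class ElementHit:
    gene_id: str
    element: str
    strand: str
    start: int  # 0-based half-open offsets within the upstream window
    end: int


def load_default_elements() -> list[CisElement]:
    """The packaged illustrative cis-element table."""
    with resources.files("mybkit.data").joinpath("cis_elements.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t")
    return [
        CisElement(r["name"], r["iupac_pattern"], r["category"])
        for _, r in df.iterrows()
    ]


def read_elements(path) -> list[CisElement]:
    df = pd.read_csv(path, sep="\t")
    return [
        CisElement(r["name"], r["iupac_pattern"], r.get("category", ""))
        for _, r in df.iterrows()
    ]


def extract_upstream(genome_seq, model: GeneModel,
                     length: int = UPSTREAM_LENGTH) -> SequenceRecord:
    """The upstream window 5' of the TSS in transcription orientation.

    For a plus-strand gene this is genomic [tss-length, tss); for a minus-
    strand gene the reverse complement of [tss, tss+length).  Windows are
    clipped at the contig edge with a warning.
    """
    seq = getattr(genome_seq, "sequence", genome_seq)
    if model.strand == "+":
        tss = min(s for s, _ in model.exons)
        lo = tss - length
        if lo < 0:
            warnings.warn(
                f"{model.gene_id}: upstream window clipped to {tss} bp at contig start"
            )
            lo = 0
        window = seq[lo:tss]
    else:
        tss = max(e for _, e in model.exons)
        hi = tss + length
        if hi > len(seq):
            warnings.warn(
                f"{model.gene_id}: upstream window clipped to {len(seq) - tss} bp "
                "at contig end"
            )
            hi = len(seq)
        window = reverse_complement(seq[tss:hi])
    return SequenceRecord(f"{model.gene_id}_upstream", window)


def _iupac_regex(pattern: str) -> re.Pattern:
    return re.compile(
        "(?=(" + "".join(f"[{IUPAC[c]}]" for c in pattern.upper()) + "))"
    )


def scan_elements(upstream, elements, both_strands: bool = True
                  ) -> list[ElementHit]:
    """All element match offsets in an upstream window, on both strands.

    Minus-strand hits are occurrences of the reverse complement of the
    pattern on the forward window; coordinates always refer to the forward
    window (offset 0 = the most upstream position).
    """
    gene_id = getattr(upstream, "id", "window")
    seq = getattr(upstream, "sequence", upstream).upper()
    hits = []
    for el in elements:
        plen = len(el.iupac_pattern)
        for m in _iupac_regex(el.iupac_pattern).finditer(seq):
            hits.append(ElementHit(gene_id, el.name, "+", m.start(), m.start() + plen))
        if both_strands:
            rc = reverse_complement(el.iupac_pattern.upper())
            for m in _iupac_regex(rc).finditer(seq):
                hits.append(
                    ElementHit(gene_id, el.name, "-", m.start(), m.start() + plen)
                )
    return sorted(hits, key=lambda h: (h.start, h.element, h.strand))


def category_counts(hits, elements) -> pd.DataFrame:
    """Per-gene per-category hit counts."""
    cat = {el.name: el.category for el in elements}
    rows = [
        {"gene_id": h.gene_id, "category": cat.get(h.element, "")}
        for h in hits
    ]
    if not rows:
        return pd.DataFrame(columns=["gene_id"])
    return (
        pd.DataFrame(rows)
        .value_counts()
        .unstack(fill_value=0)
        .rename_axis(columns=None)
        .reset_index()
    )
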