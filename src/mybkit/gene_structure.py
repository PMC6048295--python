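"""Intron counts, intron phases, and splice-site pattern classes.

An intron's phase is its splice position relative to the codon frame: phase
0 splits between codons, phase 1 after the first nucleotide of a codon,
phase 2 after the second.  Equivalently, with ``cds_offset`` the number of
coding nucleotides 5' of the splice site, phase == cds_offset mod 3 and the
affected residue index is cds_offset // 3 (0-based).

Pattern classification maps each CDS-interrupting intron onto the R2/R3
repeat coordinates of the encoded protein: the key records, in transcription
order, which region the splice site falls in (R2, R3 or outside), its
residue offset within that region, and its phase.  Keys are assigned
single-letter labels deterministically (lexicographic order over the
dataset, 'a' onward); the keys, not the letters, are the scientific content.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .io_formats import GeneModel


@dataclass(frozen=True)
class IntronRecord:
    gene_id: str
    intron_index: int  # 1-based, transcription order, CDS-interrupting only
    cds_offset: int  # coding nucleotides 5' of the splice site
    phase: int
    protein_position: int  # residue containing / immediately after the site
    flanking_residues: str = ""  # residue before and residue at the site

    def __post_init__(self):
        assert self.phase == self.cds_offset % 3
        assert self.protein_position == self.cds_offset // 3


def _cds_intervals_in_txn_order(model: GeneModel):
    ivs = list(model.cds)
    # transcription order: ascending genomic on +, descending on -
    return sorted(ivs, reverse=(model.strand == "-"))


def intron_phases(model: GeneModel, protein: str | None = None
                  ) -> tuple[list[IntronRecord], int]:
    """Phase records for every CDS-interrupting intron of a gene model.

    Returns (records, n_utr_introns); introns lying entirely in untranslated
    exons are excluded from the records but counted.  Requires a complete
    model (CDS length divisible by 3).
    """
    if not model.complete or model.cds_length % 3 != 0:
        raise ValueError(f"gene model {model.gene_id} is incomplete")
    cds = _cds_intervals_in_txn_order(model)
    records = []
    offset = 0
    # an intron interrupts the CDS iff consecutive CDS segments are separated
    for k, (s, e) in enumerate(cds):
        offset += e - s
        if k == len(cds) - 1:
            break
        phase = offset % 3
        pos = offset // 3
        # two-character context: residue 5' of the junction + the residue at
        # (phase 0) or containing (phase 1/2) the splice site
        flank = ""
        if protein is not None and pos > 0:
            flank = protein[pos - 1] + (protein[pos] if pos < len(protein) else "")
        records.append(
            IntronRecord(
                gene_id=model.gene_id,
                intron_index=k + 1,
                cds_offset=offset,
                phase=phase,
                protein_position=pos,
                flanking_residues=flank,
            )
        )
    n_utr_introns = model.n_introns - len(records)
    return records, n_utr_introns


@dataclass(frozen=True)
class IntronPattern:
    gene_id: str
    key: tuple  # ((region, offset_in_region, phase), ...)
    label: str = ""


def classify_pattern(gene_id: str, introns, repeats) -> IntronPattern:
    """Build a splice-site pattern key relative to R2/R3 repeat spans.

    ``repeats`` are the scanner's MybRepeat hits for the same gene's
    protein.  A site exactly on a repeat boundary belongs to the repeat via
    the closed-start/open-end convention of the half-open spans.  Offsets
    are residues from the repeat start (phase 0: the residue after the
    junction; phase 1/2: the split residue).
    """
    spans = {r.repeat_label: (r.start, r.end) for r in repeats
             if r.repeat_label in ("R2", "R3")}
    key = []
    for rec in introns:
        pos = rec.protein_position
        region, offset = "outside", pos
        for label in ("R2", "R3"):
            if label in spans:
                s, e = spans[label]
                if s <= pos < e:
                    region, offset = label, pos - s
                    break
        key.append((region, offset, rec.phase))
    return IntronPattern(gene_id, tuple(key))


def assign_pattern_labels(patterns) -> list[IntronPattern]:
    """Deterministically label patterns: lexicographic key order, 'a' onward.

    Identical keys get identical labels; beyond 26 distinct keys labels
    continue 'aa', 'ab', ...
    """
    def letters(i: int) -> str:
        out = ""
        while True:
            out = chr(ord("a") + i % 26) + out
            i = i // 26 - 1
            if i < 0:
                return out

    distinct = sorted({p.key for p in patterns})
    label_of = {key: letters(i) for i, key in enumerate(distinct)}
    return [IntronPattern(p.gene_id, p.key, label_of[p.key]) for p in patterns]


def structure_summary(models, patterns) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-gene structure table plus the pattern-label distribution.

    Returns (per_gene, distribution): per_gene has gene_id, n_introns_cds,
    n_introns_total, n_exons and pattern label; distribution lists each
    label with its count and percentage (summing to 100 up to rounding).
    """
    by_gene = {p.gene_id: p for p in patterns}
    rows = []
    for m in models:
        pat = by_gene.get(m.gene_id)
        recs, n_utr = intron_phases(m)
        rows.append(
            {
                "gene_id": m.gene_id,
                "n_introns_cds": len(recs),
                "n_introns_total": m.n_introns,
                "n_exons": len(m.exons),
                "pattern": pat.label if pat else "",
            }
        )
    per_gene = pd.DataFrame(rows)
    counts = per_gene["pattern"].value_counts().sort_index()
    distribution = pd.DataFrame(
        {
            "pattern": counts.index,
            "count": counts.values,
            "percent": (100.0 * counts / counts.sum()).round(1).values,
        }
    )
    return per_gene, distribution
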