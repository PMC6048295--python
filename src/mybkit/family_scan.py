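"""MYB repeat detection, family classification and physicochemical profiles.

The MYB DNA-binding repeat is a ~52-residue helix-turn-helix unit with three
regularly spaced tryptophans forming its hydrophobic core.  Plant MYB
proteins fall into families by repeat count: one repeat -> MYB-related, two
-> R2R3, three -> R1R2R3, four -> 4R.  Detection here uses a position-weight
(log-odds) model over a fixed-length window; the packaged default model is
built from a small synthetic alignment around the canonical plant R2/R3
consensus (shipped in ``data/r2r3_repeat_alignment.synthetic.fasta``) and is
fully configurable.

Landmark tryptophan columns are annotated, never enforced: a repeat whose
landmark W is substituted (as happens in the ancient clade of this family,
where W is replaced by M/R in the R2 repeat and A in the R3 repeat) is still
reported, with the observed residues recorded.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
from Bio.SeqUtils.ProtParam import ProteinAnalysis

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}

#: default pKa set (EMBOSS values); pI depends on the table, so it is data
DEFAULT_PKA = {
    "Nterm": 8.6,
    "Cterm": 3.6,
    "K": 10.8,
    "R": 12.5,
    "H": 6.5,
    "D": 3.9,
    "E": 4.1,
    "C": 8.5,
    "Y": 10.1,
}

#: z-score above the null window-score mean used for the default threshold
DEFAULT_THRESHOLD_Z = 6.0


@dataclass
class RepeatModel:
    """Position-weight model for one ~52-aa MYB repeat.

    ``position_weights`` holds per-column log2 odds versus a uniform
    background; ``frequencies`` the (pseudocounted) column residue
    frequencies the weights derive from.  ``landmark_positions`` are the
    columns whose training consensus is tryptophan.
    """

    position_weights: np.ndarray  # (length, 20)
    frequencies: np.ndarray  # (length, 20)
    landmark_positions: tuple[int, ...]
    score_threshold: float

    def __post_init__(self):
        if self.position_weights.shape != self.frequencies.shape:
            raise ValueError("weights and frequencies shape mismatch")
        if not math.isfinite(self.score_threshold):
            raise ValueError("score threshold must be finite")

    @property
    def length(self) -> int:
        return self.position_weights.shape[0]

    def window_score(self, window: str) -> float:
        total = 0.0
        for c, res in enumerate(window):
            idx = _AA_INDEX.get(res)
            if idx is None:
                continue  # non-canonical residue contributes nothing
            total += self.position_weights[c, idx]
        return total

    def null_moments(self) -> tuple[float, float]:
        """Mean and sd of the window score under a uniform iid background."""
        mu = self.position_weights.mean(axis=1)
        var = (self.position_weights ** 2).mean(axis=1) - mu ** 2
        return float(mu.sum()), float(math.sqrt(var.sum()))

    @classmethod
    def from_alignment(cls, rows, pseudocount: float = 0.5,
                       threshold_z: float = DEFAULT_THRESHOLD_Z) -> "RepeatModel":
        """Build the model from equal-length aligned repeat sequences.

        The default score threshold is set ``threshold_z`` standard
        deviations above the null (uniform background) window-score mean,
        which makes chance hits in random sequence vanishingly rare while
        leaving a wide margin for diverged real repeats.
        """
        rows = list(rows)
        length = len(rows[0])
        if any(len(r) != length for r in rows):
            raise ValueError("repeat alignment rows must have equal length")
        counts = np.full((length, 20), pseudocount)
        for r in rows:
            for c, res in enumerate(r.upper()):
                if res in _AA_INDEX:
                    counts[c, _AA_INDEX[res]] += 1
        freqs = counts / counts.sum(axis=1, keepdims=True)
        weights = np.log2(freqs / (1.0 / 20.0))
        landmarks = tuple(
            c for c in range(length)
            if pd.Series([r[c] for r in rows]).mode()[0] == "W"
        )
        model = cls(weights, freqs, landmarks, 0.0)
        mu0, sd0 = model.null_moments()
        model.score_threshold = mu0 + threshold_z * sd0
        return model


def default_repeat_model() -> RepeatModel:
    """The packaged R2/R3 repeat model (synthetic consensus alignment)."""
    from .io_formats import read_fasta

    path = resources.files("mybkit.data").joinpath(
        "r2r3_repeat_alignment.synthetic.fasta"
    )
    with resources.as_file(path) as p:
        records = read_fasta(p, alphabet="aa")
    return RepeatModel.from_alignment([r.sequence for r in records])


@dataclass(frozen=True)
class MybRepeat:
    """One detected repeat: 0-based half-open protein span."""

    start: int
    end: int
    score: float
    landmark_residues: str
    repeat_label: str = ""


def scan_repeats(protein, model: RepeatModel | None = None) -> list[MybRepeat]:
    """Detect MYB repeats in a protein with a sliding position-weight window.

    All windows scoring at or above the model threshold are collected, then
    resolved to a non-overlapping set greedily by descending score (ties:
    leftmost), and the survivors are labelled in N->C order: R1/R2/R3 for
    three, R2/R3 for the canonical two-repeat arrangement, extras R-extra.
    A protein shorter than the model yields an empty list.
    """
    if model is None:
        model = default_repeat_model()
    seq = getattr(protein, "sequence", protein)
    L = model.length
    if len(seq) < L:
        return []
    # vectorized window scores: non-canonical residues contribute 0
    idx = np.array([_AA_INDEX.get(r, 20) for r in seq])
    weights = np.hstack([model.position_weights, np.zeros((L, 1))])
    n_win = len(seq) - L + 1
    scores = np.zeros(n_win)
    for c in range(L):
        scores += weights[c, idx[c:c + n_win]]
    hits = [
        (float(scores[start]), start)
        for start in range(n_win)
        if scores[start] >= model.score_threshold
    ]
    hits.sort(key=lambda h: (-h[0], h[1]))
    chosen: list[tuple[float, int]] = []
    for score, start in hits:
        if all(start + L <= s or start >= s + L for _, s in chosen):
            chosen.append((score, start))
    chosen.sort(key=lambda h: h[1])
    labels = {2: ["R2", "R3"], 3: ["R1", "R2", "R3"]}.get(
        len(chosen),
        [f"R{i + 1}" if i < 3 else "R-extra" for i in range(len(chosen))],
    )
    out = []
    for (score, start), label in zip(chosen, labels):
        landmark = "".join(seq[start + c] for c in model.landmark_positions)
        out.append(
            MybRepeat(start, start + L, score, landmark, label)
        )
    return out


@dataclass(frozen=True)
class FamilyClass:
    gene_id: str
    n_repeats: int
    family: str


_FAMILY_BY_COUNT = {0: "none", 1: "MYB-related", 2: "R2R3", 3: "R1R2R3"}


def classify_family(gene_id: str, repeats) -> FamilyClass:
    """Family from repeat count: 1 -> MYB-related, 2 -> R2R3, 3 -> R1R2R3,
    >=4 -> 4R, 0 -> none.  (Genes with two or more repeats form the R2R3
    superfamily sensu lato.)"""
    n = len(repeats)
    family = _FAMILY_BY_COUNT.get(n, "4R")
    return FamilyClass(gene_id, n, family)


# ---------------------------------------------------------------------------
# Physicochemical profile
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PhysChemProfile:
    gravy: float
    pi: float
    mw: float


def _net_charge(seq: str, ph: float, pka: dict) -> float:
    pos = 1.0 / (1.0 + 10 ** (ph - pka["Nterm"]))
    neg = 1.0 / (1.0 + 10 ** (pka["Cterm"] - ph))
    for res in seq:
        if res in ("K", "R", "H"):
            pos += 1.0 / (1.0 + 10 ** (ph - pka[res]))
        elif res in ("D", "E", "C", "Y"):
            neg += 1.0 / (1.0 + 10 ** (pka[res] - ph))
    return pos - neg


def isoelectric_point(seq: str, pka: dict | None = None, tol: float = 1e-4) -> float:
    """pI by bisection of the net-charge curve (monotone decreasing in pH)."""
    pka = pka or DEFAULT_PKA
    lo, hi = 0.0, 14.0
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if _net_charge(seq, mid, pka) > 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def physchem(protein, pka: dict | None = None) -> PhysChemProfile:
    """GRAVY (mean Kyte-Doolittle hydropathy), pI and molecular weight.

    Only the 20 canonical residues are accepted; anything else raises with
    the offending position.
    """
    seq = getattr(protein, "sequence", protein).upper()
    for i, res in enumerate(seq):
        if res not in _AA_INDEX:
            raise ValueError(f"non-canonical residue {res!r} at position {i}")
    pa = ProteinAnalysis(seq)
    return PhysChemProfile(
        gravy=pa.gravy(),
        pi=isoelectric_point(seq, pka),
        mw=pa.molecular_weight(),
    )


# ---------------------------------------------------------------------------
# Sequence logos
# ---------------------------------------------------------------------------

def logo_matrix(rows) -> tuple[pd.DataFrame, pd.Series, pd.Series]:
    """Per-column residue frequencies and information content of an
    alignment of repeat sequences.

    Gaps are excluded from the frequency denominator and reported separately
    as a per-column gap fraction.  IC = log2(20) - Shannon entropy, with no
    small-sample correction.
    """
    rows = [r.upper() for r in rows]
    length = len(rows[0])
    if any(len(r) != length for r in rows):
        raise ValueError("logo input rows must have equal length")
    freq = pd.DataFrame(0.0, index=list(AMINO_ACIDS), columns=range(length))
    gap_frac = pd.Series(0.0, index=range(length))
    ic = pd.Series(0.0, index=range(length))
    for c in range(length):
        col = [r[c] for r in rows]
        residues = [x for x in col if x in _AA_INDEX]
        gap_frac[c] = 1.0 - len(residues) / len(col)
        if not residues:
            ic[c] = float("nan")
            continue
        counts = pd.Series(residues).value_counts()
        p = counts / counts.sum()
        freq.loc[p.index, c] = p.values
        entropy = -(p * np.log2(p)).sum()
        ic[c] = math.log2(20) - entropy
    return freq, ic, gap_frac


def family_table(proteins, model: RepeatModel | None = None) -> pd.DataFrame:
    """Scan + classify + profile a set of proteins into one summary frame."""
    if model is None:
        model = default_repeat_model()
    rows = []
    for rec in proteins:
        repeats = scan_repeats(rec, model)
        fam = classify_family(rec.id, repeats)
        prof = physchem(rec)
        rows.append(
            {
                "gene_id": rec.id,
                "n_repeats": fam.n_repeats,
                "family": fam.family,
                "gravy": prof.gravy,
                "pi": prof.pi,
                "mw": prof.mw,
            }
        )
    return pd.DataFrame(rows)
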