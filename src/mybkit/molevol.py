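"""Nei-Gojobori (NG86) Ka/Ks estimation, molecular-clock dating, and
ortholog/paralog pairing.

The counting method follows the unweighted NG86 convention: per-codon
synonymous site fractions from the universal genetic code, with mutations to
stop codons counted as nonsynonymous in site counting; codon pairs differing
at several positions are averaged over all mutational pathways with equal
weight, excluding pathways that pass through a stop codon; proportions are
corrected for multiple hits with the Jukes-Cantor formula
d = -(3/4) ln(1 - (4/3) p).

Divergence dates use the grass-clade synonymous clock
T = Ks / (2 * lambda), lambda = 6.5e-9 substitutions/site/year, reported in
millions of years (MYA).
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass
from importlib import resources

import pandas as pd
from Bio.Data.CodonTable import standard_dna_table

BASES = "ACGT"
STOP_CODONS = frozenset(standard_dna_table.stop_codons)
_FORWARD = dict(standard_dna_table.forward_table)

#: synonymous-substitution clock rate for grasses, substitutions/site/year
CLOCK_RATE = 6.5e-9

#: half-width of the neutral band around Ka/Ks = 1 (floats are never exactly 1)
NEUTRAL_EPSILON = 0.05


def translate_codon(codon: str) -> str:
    """Amino acid for a codon; '*' for a stop."""
    if codon in STOP_CODONS:
        return "*"
    try:
        return _FORWARD[codon]
    except KeyError:
        raise ValueError(f"not an unambiguous codon: {codon!r}") from None


def translate_cds(cds: str) -> str:
    if len(cds) % 3 != 0:
        raise ValueError("CDS length not divisible by 3")
    return "".join(translate_codon(cds[i:i + 3]) for i in range(0, len(cds), 3))


def codon_neighbors(codon: str):
    """All single-nucleotide, non-stop neighbors as (pos, alt_codon, is_syn)."""
    aa = translate_codon(codon)
    out = []
    for pos in range(3):
        for b in BASES:
            if b == codon[pos]:
                continue
            alt = codon[:pos] + b + codon[pos + 1:]
            if alt in STOP_CODONS:
                continue
            out.append((pos, alt, translate_codon(alt) == aa))
    return out


def synonymous_fraction(codon: str) -> float:
    """NG86 synonymous site count for one codon (0..3).

    Each position contributes (# synonymous one-step changes)/3; changes to
    stop codons count as nonsynonymous.
    """
    aa = translate_codon(codon)
    s = 0.0
    for pos in range(3):
        for b in BASES:
            if b == codon[pos]:
                continue
            alt = codon[:pos] + b + codon[pos + 1:]
            if alt not in STOP_CODONS and translate_codon(alt) == aa:
                s += 1.0 / 3.0
    return s


def pathway_differences(codon_a: str, codon_b: str) -> tuple[float, float]:
    """Pathway-averaged (Sd, Nd) between two codons.

    All orderings of the differing positions are enumerated; pathways passing
    through a stop codon are excluded.  If every pathway is blocked by stops
    (possible only for 3-fold differences between rare codons) all pathways
    are used, counting the stop steps as nonsynonymous.
    """
    diff = [i for i in range(3) if codon_a[i] != codon_b[i]]
    if not diff:
        return 0.0, 0.0
    for allow_stops in (False, True):
        tot_s = tot_n = 0.0
        n_paths = 0
        for order in itertools.permutations(diff):
            cur = codon_a
            s = n = 0
            ok = True
            for pos in order:
                nxt = cur[:pos] + codon_b[pos] + cur[pos + 1:]
                if nxt in STOP_CODONS and not allow_stops:
                    ok = False
                    break
                if translate_codon(nxt) == translate_codon(cur):
                    s += 1
                else:
                    n += 1
                cur = nxt
            if ok:
                tot_s += s
                tot_n += n
                n_paths += 1
        if n_paths:
            return tot_s / n_paths, tot_n / n_paths
    raise AssertionError("unreachable")


@dataclass(frozen=True)
class CodonAlignment:
    """Two gapped CDS strings whose gap runs are in-frame triples."""

    seq_a: str
    seq_b: str

    def __post_init__(self):
        if len(self.seq_a) != len(self.seq_b):
            raise ValueError("aligned CDS rows differ in length")
        if len(self.seq_a) % 3 != 0:
            raise ValueError("codon alignment length not divisible by 3")
        for seq in (self.seq_a, self.seq_b):
            for i in range(0, len(seq), 3):
                cod = seq[i:i + 3]
                if "-" in cod and cod != "---":
                    raise ValueError(f"out-of-frame gap in codon {cod!r}")

    def codon_pairs(self):
        """Gap-free, unambiguous codon pairs."""
        pairs = []
        for i in range(0, len(self.seq_a), 3):
            ca, cb = self.seq_a[i:i + 3], self.seq_b[i:i + 3]
            if "-" in ca or "-" in cb:
                continue
            if set(ca + cb) - set(BASES):
                continue
            if ca in STOP_CODONS or cb in STOP_CODONS:
                continue
            pairs.append((ca, cb))
        return pairs


def codon_align(protein_alignment, cds_a: str, cds_b: str) -> CodonAlignment:
    """Back-translate a 2-row protein alignment onto its CDS sequences.

    Each CDS must translate exactly to its ungapped protein row (a terminal
    stop codon is allowed and trimmed); protein gaps become '---'.
    """
    rows = list(protein_alignment)
    if len(rows) != 2:
        raise ValueError("codon_align needs a pairwise protein alignment")
    out = []
    for gapped, cds in zip(rows, (cds_a, cds_b)):
        cds = cds.upper().replace("U", "T")
        prot = translate_cds(cds)
        if prot.endswith("*"):
            prot = prot[:-1]
            cds = cds[:-3]
        ungapped = gapped.replace("-", "")
        if prot != ungapped:
            idx = next(
                (i for i, (x, y) in enumerate(zip(prot, ungapped)) if x != y),
                min(len(prot), len(ungapped)),
            )
            raise ValueError(
                f"CDS translation does not match protein row at residue {idx}"
            )
        if "*" in prot:
            raise ValueError("CDS contains an internal stop codon")
        pieces = []
        k = 0
        for ch in gapped:
            if ch == "-":
                pieces.append("---")
            else:
                pieces.append(cds[3 * k:3 * k + 3])
                k += 1
        out.append("".join(pieces))
    return CodonAlignment(out[0], out[1])


class SaturationError(ValueError):
    """Observed proportion of differences too high for the JC correction."""


def jukes_cantor(p: float) -> float:
    if p >= 0.75:
        raise SaturationError(f"proportion {p:.3f} >= 0.75: distance saturated")
    return -0.75 * math.log(1.0 - (4.0 / 3.0) * p) + 0.0


@dataclass(frozen=True)
class KaKsResult:
    """NG86 site/difference counts, rates, and the clock date for one pair."""

    S: float
    N: float
    Sd: float
    Nd: float
    ps: float
    pn: float
    ks: float
    ka: float
    ratio: float  # NaN when ks == 0
    t_mya: float
    lam: float = CLOCK_RATE

    @property
    def n_codons(self) -> float:
        return (self.S + self.N) / 3.0


def nei_gojobori(ca: CodonAlignment, lam: float = CLOCK_RATE) -> KaKsResult:
    """Estimate Ka and Ks between two aligned CDS with the NG86 method."""
    pairs = ca.codon_pairs()
    if not pairs:
        raise ValueError("no comparable (gap-free, unambiguous) codon pairs")
    s_a = s_b = sd = nd = 0.0
    for cod_a, cod_b in pairs:
        s_a += synonymous_fraction(cod_a)
        s_b += synonymous_fraction(cod_b)
        ds, dn = pathway_differences(cod_a, cod_b)
        sd += ds
        nd += dn
    S = 0.5 * (s_a + s_b)
    N = 3.0 * len(pairs) - S
    if S <= 0:
        raise ValueError("no synonymous sites in alignment")
    ps, pn = sd / S, nd / N
    ks, ka = jukes_cantor(ps), jukes_cantor(pn)
    ratio = ka / ks if ks > 0 else float("nan")
    return KaKsResult(
        S=S, N=N, Sd=sd, Nd=nd, ps=ps, pn=pn, ks=ks, ka=ka,
        ratio=ratio, t_mya=divergence_time(ks, lam), lam=lam,
    )


def divergence_time(ks: float, lam: float = CLOCK_RATE) -> float:
    """Molecular-clock date in MYA: T = Ks / (2 * lambda) / 1e6."""
    if ks < 0:
        raise ValueError("ks must be non-negative")
    return ks / (2.0 * lam) / 1e6


@dataclass(frozen=True)
class SelectionCall:
    regime: str  # purifying | neutral | positive | undetermined
    ratio: float


def classify_selection(ratio: float, epsilon: float = NEUTRAL_EPSILON) -> SelectionCall:
    """Selection regime from Ka/Ks: <1 purifying, =1 neutral, >1 positive.

    Exact float equality with 1 is meaningless, so "neutral" is an epsilon
    band |ratio - 1| <= epsilon.  NaN (undefined ratio) -> "undetermined".
    """
    if math.isnan(ratio):
        return SelectionCall("undetermined", ratio)
    if ratio < 0:
        raise ValueError("Ka/Ks ratio cannot be negative")
    if ratio < 1.0 - epsilon:
        return SelectionCall("purifying", ratio)
    if ratio > 1.0 + epsilon:
        return SelectionCall("positive", ratio)
    return SelectionCall("neutral", ratio)


# ---------------------------------------------------------------------------
# Reciprocal best hits
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GenePair:
    id_a: str
    id_b: str
    relation: str  # "paralog" | "ortholog"
    evidence: str = "RBH"

    def __post_init__(self):
        if self.id_a == self.id_b:
            raise ValueError("a gene cannot pair with itself")


def rbh_pairs(set_a, set_b, scorer=None, relation: str | None = None):
    """Reciprocal-best-hit pairs between two protein sets.

    ``scorer(seq_a, seq_b) -> float`` defaults to the affine-gap global
    alignment score (BLOSUM62).  A pair is reported iff each member is the
    other's unique best hit; tied best scores drop the pair with a warning.
    Passing the same set twice finds paralog pairs (self-hits excluded).
    """
    if scorer is None:
        from .phylo import alignment_score

        scorer = alignment_score
    same = {r.id for r in set_a} == {r.id for r in set_b}
    if relation is None:
        relation = "paralog" if same else "ortholog"
    if not set_a or not set_b:
        raise ValueError("both input sets must be non-empty")

    def best_hits(queries, targets):
        best = {}
        for q in queries:
            scored = [
                (scorer(q.sequence, t.sequence), t.id)
                for t in targets
                if t.id != q.id
            ]
            if not scored:
                continue
            top = max(s for s, _ in scored)
            winners = [tid for s, tid in scored if s == top]
            if len(winners) > 1:
                warnings.warn(
                    f"tied best hits for {q.id}: {sorted(winners)}; pair dropped"
                )
                best[q.id] = None
            else:
                best[q.id] = winners[0]
        return best

    fwd = best_hits(set_a, set_b)
    rev = best_hits(set_b, set_a)
    pairs = []
    seen = set()
    for a_id, b_id in fwd.items():
        if b_id is None or rev.get(b_id) != a_id:
            continue
        key = frozenset((a_id, b_id))
        if key in seen:
            continue
        seen.add(key)
        pairs.append(GenePair(a_id, b_id, relation=relation))
    return pairs


# ---------------------------------------------------------------------------
# Published divergence estimates (moso bamboo MYB gene pairs)
# ---------------------------------------------------------------------------

def load_divergence_table() -> pd.DataFrame:
    """Published Ka/Ks estimates for moso bamboo MYB ortholog/paralog pairs.

    Columns: gene_a, gene_b, relation, ks, ka, ratio_published,
    mya_published.  The ratio and MYA columns are closed-form functions of
    the printed Ka and Ks and serve as a worked reference set for
    :func:`divergence_time` and ratio computation.
    """
    with resources.files("mybkit.data").joinpath(
        "phe_myb_divergence_pairs.tsv"
    ).open() as fh:
        return pd.read_csv(fh, sep="\t")


def kaks_table(pairs_cds, lam: float = CLOCK_RATE, epsilon: float = NEUTRAL_EPSILON):
    """Run the full per-pair analysis: NG86 + dating + selection call.

    ``pairs_cds`` yields (name_a, name_b, CodonAlignment).  Returns a
    DataFrame with the columns of the published table plus the regime.
    """
    rows = []
    for name_a, name_b, ca in pairs_cds:
        r = nei_gojobori(ca, lam=lam)
        rows.append(
            {
                "gene_a": name_a,
                "gene_b": name_b,
                "S": r.S,
                "N": r.N,
                "ks": r.ks,
                "ka": r.ka,
                "ratio": r.ratio,
                "mya": r.t_mya,
                "regime": classify_selection(r.ratio, epsilon).regime,
            }
        )
    return pd.DataFrame(rows)
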