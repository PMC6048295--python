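"""Alignment, distance estimation, neighbor joining and bootstrap supports.

The tree container is a :class:`dendropy.Tree`; the algorithms (Gotoh
affine-gap alignment, progressive profile MSA, Saitou-Nei neighbor joining,
column-bootstrap supports) are implemented here with the tie-breaking rules
spelled out so outputs are bit-reproducible:

* pairwise traceback prefers match, then a gap in sequence b, then a gap in
  sequence a;
* NJ ties on the Q criterion are broken by the smallest (i, j) index pair;
* negative NJ branch-length estimates are clamped to zero with a warning.
"""

from __future__ import annotations

import math
import warnings
from collections import Counter
from dataclasses import dataclass, field

import dendropy
import numpy as np
from Bio.Align import substitution_matrices

DEFAULT_GAP_OPEN = 10.0
DEFAULT_GAP_EXTEND = 0.5

_AA = set("ACDEFGHIKLMNPQRSTVWYBXZJUO")
_NT = set("ACGTUN")


def _load_table(table):
    if table is None or isinstance(table, str):
        return substitution_matrices.load(table or "BLOSUM62")
    return table


def _check_alphabets(a: str, b: str):
    def kind(s):
        letters = set(s)
        if letters - _AA:
            raise ValueError(
                f"unrecognized alphabet in sequence: {sorted(letters - _AA)}"
            )
        # short ACG-only strings are valid protein fragments; call a sequence
        # nucleotide only on positive evidence (T/U present, no aa-only letters)
        if letters <= _NT and letters & {"T", "U"}:
            return "nt"
        return "aa"

    if kind(a) != kind(b):
        raise ValueError("alphabet mismatch between sequences")


@dataclass
class Alignment:
    """Equal-length gapped rows keyed by sequence id."""

    ids: list[str]
    rows: list[str]

    def __post_init__(self):
        if len(self.ids) != len(self.rows):
            raise ValueError("ids and rows differ in length")
        if len({len(r) for r in self.rows}) > 1:
            raise ValueError("alignment rows have unequal lengths")

    def __len__(self):
        return len(self.rows[0]) if self.rows else 0

    def __iter__(self):
        return iter(self.rows)

    def ungapped(self, i: int) -> str:
        return self.rows[i].replace("-", "")

    def columns(self):
        return ["".join(col) for col in zip(*self.rows)]


NEG = -1e30


def _gotoh(a: str, b: str, table, gap_open: float, gap_extend: float,
           traceback: bool = True):
    """Affine-gap global alignment (gap of length L costs open + L*extend).

    Returns (score, gapped_a, gapped_b); the traceback tie-break prefers
    match/mismatch, then a gap in b (consume a), then a gap in a.
    """
    n, m = len(a), len(b)
    sub = np.empty((n, m))
    for i, ra in enumerate(a):
        for j, rb in enumerate(b):
            sub[i, j] = table[ra, rb]
    go, ge = gap_open + gap_extend, gap_extend
    M = np.full((n + 1, m + 1), NEG)
    X = np.full((n + 1, m + 1), NEG)  # gap in b: consumes a
    Y = np.full((n + 1, m + 1), NEG)  # gap in a: consumes b
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        X[i, 0] = -(gap_open + i * ge)
    for j in range(1, m + 1):
        Y[0, j] = -(gap_open + j * ge)
    for i in range(1, n + 1):
        Mi, Mi1 = M[i], M[i - 1]
        Xi, Xi1 = X[i], X[i - 1]
        Yi = Y[i]
        Y1 = Y[i - 1]
        si = sub[i - 1]
        for j in range(1, m + 1):
            best = Mi1[j - 1]
            if Xi1[j - 1] > best:
                best = Xi1[j - 1]
            if Y1[j - 1] > best:
                best = Y1[j - 1]
            Mi[j] = best + si[j - 1]
            Xi[j] = max(Mi1[j] - go, Xi1[j] - ge, Y1[j] - go)
            Yi[j] = max(Mi[j - 1] - go, Yi[j - 1] - ge, Xi[j - 1] - go)
    score = max(M[n, m], X[n, m], Y[n, m])
    if not traceback:
        return score, None, None
    # deterministic traceback: state preference M > X > Y at equal score
    ga, gb = [], []
    i, j = n, m
    state = "M" if M[n, m] == score else ("X" if X[n, m] == score else "Y")
    while i > 0 or j > 0:
        if state == "M":
            ga.append(a[i - 1])
            gb.append(b[j - 1])
            target = M[i, j] - sub[i - 1, j - 1]
            i, j = i - 1, j - 1
            for s, mat in (("M", M), ("X", X), ("Y", Y)):
                if math.isclose(mat[i, j], target, rel_tol=0, abs_tol=1e-9):
                    state = s
                    break
        elif state == "X":
            ga.append(a[i - 1])
            gb.append("-")
            val = X[i, j]
            i -= 1
            if math.isclose(M[i, j] - go, val, abs_tol=1e-9):
                state = "M"
            elif math.isclose(X[i, j] - ge, val, abs_tol=1e-9):
                state = "X"
            else:
                state = "Y"
        else:
            ga.append("-")
            gb.append(b[j - 1])
            val = Y[i, j]
            j -= 1
            if math.isclose(M[i, j] - go, val, abs_tol=1e-9):
                state = "M"
            elif math.isclose(Y[i, j] - ge, val, abs_tol=1e-9):
                state = "Y"
            else:
                state = "X"
        if i == 0 and j > 0:
            state = "Y"
        elif j == 0 and i > 0:
            state = "X"
    return score, "".join(reversed(ga)), "".join(reversed(gb))


def global_align(a, b, substitution_table=None, gap_open: float = DEFAULT_GAP_OPEN,
                 gap_extend: float = DEFAULT_GAP_EXTEND):
    """Optimal affine-gap global alignment of two sequences.

    ``a`` and ``b`` may be strings or SequenceRecords.  Returns
    (:class:`Alignment`, score).
    """
    id_a, id_b = getattr(a, "id", "a"), getattr(b, "id", "b")
    sa = getattr(a, "sequence", a)
    sb = getattr(b, "sequence", b)
    if not sa or not sb:
        raise ValueError("cannot align an empty sequence")
    _check_alphabets(sa, sb)
    table = _load_table(substitution_table)
    score, ga, gb = _gotoh(sa, sb, table, gap_open, gap_extend)
    return Alignment([id_a, id_b], [ga, gb]), score


def alignment_score(a, b, substitution_table=None, gap_open: float = DEFAULT_GAP_OPEN,
                    gap_extend: float = DEFAULT_GAP_EXTEND) -> float:
    """Global alignment score only (used as the default RBH scorer)."""
    sa = getattr(a, "sequence", a)
    sb = getattr(b, "sequence", b)
    if not sa or not sb:
        raise ValueError("cannot align an empty sequence")
    _check_alphabets(sa, sb)
    table = _load_table(substitution_table)
    score, _, _ = _gotoh(sa, sb, table, gap_open, gap_extend, traceback=False)
    return score


# ---------------------------------------------------------------------------
# Progressive multiple alignment
# ---------------------------------------------------------------------------

def kmer_distance_matrix(records, k: int = 3) -> "DistanceMatrix":
    """Fractional common k-mer distance used for the MSA guide tree."""
    ids = [r.id for r in records]
    counts = [Counter(r.sequence[i:i + k] for i in range(len(r.sequence) - k + 1))
              for r in records]
    n = len(records)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            common = sum((counts[i] & counts[j]).values())
            denom = min(sum(counts[i].values()), sum(counts[j].values()))
            d[i, j] = d[j, i] = 1.0 - common / denom if denom else 1.0
    return DistanceMatrix(ids, d)


def _profile_columns(rows):
    ncol = len(rows[0])
    cols = []
    for j in range(ncol):
        cols.append(Counter(r[j] for r in rows))
    return cols


def _col_score(ca: Counter, cb: Counter, table) -> float:
    na = sum(ca.values())
    nb = sum(cb.values())
    total = 0.0
    for ra, fa in ca.items():
        if ra == "-":
            continue
        for rb, fb in cb.items():
            if rb == "-":
                continue
            total += fa * fb * table[ra, rb]
    return total / (na * nb)


def _align_profiles(rows_a, rows_b, table, gap_open, gap_extend):
    """Gotoh on column profiles; returns merged gapped rows (a's then b's)."""
    cols_a = _profile_columns(rows_a)
    cols_b = _profile_columns(rows_b)
    n, m = len(cols_a), len(cols_b)
    sub = np.empty((n, m))
    for i in range(n):
        for j in range(m):
            sub[i, j] = _col_score(cols_a[i], cols_b[j], table)
    go, ge = gap_open + gap_extend, gap_extend
    M = np.full((n + 1, m + 1), NEG)
    X = np.full((n + 1, m + 1), NEG)
    Y = np.full((n + 1, m + 1), NEG)
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        X[i, 0] = -(gap_open + i * ge)
    for j in range(1, m + 1):
        Y[0, j] = -(gap_open + j * ge)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            M[i, j] = max(M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1]) + sub[i - 1, j - 1]
            X[i, j] = max(M[i - 1, j] - go, X[i - 1, j] - ge, Y[i - 1, j] - go)
            Y[i, j] = max(M[i, j - 1] - go, Y[i, j - 1] - ge, X[i, j - 1] - go)
    i, j = n, m
    score = max(M[i, j], X[i, j], Y[i, j])
    state = "M" if M[i, j] == score else ("X" if X[i, j] == score else "Y")
    steps = []
    while i > 0 or j > 0:
        if state == "M":
            steps.append("M")
            target = M[i, j] - sub[i - 1, j - 1]
            i, j = i - 1, j - 1
            for s, mat in (("M", M), ("X", X), ("Y", Y)):
                if math.isclose(mat[i, j], target, abs_tol=1e-9):
                    state = s
                    break
        elif state == "X":
            steps.append("X")
            val = X[i, j]
            i -= 1
            state = ("M" if math.isclose(M[i, j] - go, val, abs_tol=1e-9)
                     else "X" if math.isclose(X[i, j] - ge, val, abs_tol=1e-9)
                     else "Y")
        else:
            steps.append("Y")
            val = Y[i, j]
            j -= 1
            state = ("M" if math.isclose(M[i, j] - go, val, abs_tol=1e-9)
                     else "Y" if math.isclose(Y[i, j] - ge, val, abs_tol=1e-9)
                     else "X")
        if i == 0 and j > 0:
            state = "Y"
        elif j == 0 and i > 0:
            state = "X"
    steps.reverse()
    out_a = ["" for _ in rows_a]
    out_b = ["" for _ in rows_b]
    ia = ib = 0
    for s in steps:
        if s in "MX":
            for t, r in enumerate(rows_a):
                out_a[t] += r[ia]
            ia += 1
        else:
            for t in range(len(rows_a)):
                out_a[t] += "-"
        if s in "MY":
            for t, r in enumerate(rows_b):
                out_b[t] += r[ib]
            ib += 1
        else:
            for t in range(len(rows_b)):
                out_b[t] += "-"
    return out_a, out_b


def progressive_msa(records, guide=None, substitution_table=None,
                    gap_open: float = DEFAULT_GAP_OPEN,
                    gap_extend: float = DEFAULT_GAP_EXTEND) -> Alignment:
    """Minimal progressive multiple alignment.

    The merge schedule comes from neighbor joining on k-mer distances unless
    a ``guide`` join order (list of index pairs) is supplied.  Profiles are
    merged by pairwise profile alignment with affine gaps.
    """
    records = list(records)
    if len(records) < 2:
        raise ValueError("progressive_msa needs >= 2 records")
    table = _load_table(substitution_table)
    if len(records) == 2:
        aln, _ = global_align(records[0], records[1], table, gap_open, gap_extend)
        return aln
    if guide is None:
        dm = kmer_distance_matrix(records)
        guide = _nj_join_order(dm.matrix.copy())
    groups = [([r.id], [r.sequence]) for r in records]
    active = list(range(len(records)))
    for i, j in guide:
        ids_a, rows_a = groups[i]
        ids_b, rows_b = groups[j]
        out_a, out_b = _align_profiles(rows_a, rows_b, table, gap_open, gap_extend)
        groups.append((ids_a + ids_b, out_a + out_b))
        active = [a for a in active if a not in (i, j)] + [len(groups) - 1]
    while len(active) > 1:
        i, j = active[0], active[1]
        ids_a, rows_a = groups[i]
        ids_b, rows_b = groups[j]
        out_a, out_b = _align_profiles(rows_a, rows_b, table, gap_open, gap_extend)
        groups.append((ids_a + ids_b, out_a + out_b))
        active = active[2:] + [len(groups) - 1]
    ids, rows = groups[active[0]]
    order = {r.id: k for k, r in enumerate(records)}
    pairs = sorted(zip(ids, rows), key=lambda p: order[p[0]])
    return Alignment([p[0] for p in pairs], [p[1] for p in pairs])


# ---------------------------------------------------------------------------
# Distances
# ---------------------------------------------------------------------------

@dataclass
class DistanceMatrix:
    ids: list[str]
    matrix: np.ndarray

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (len(self.ids), len(self.ids)):
            raise ValueError("distance matrix shape does not match ids")
        if not np.allclose(m, m.T):
            raise ValueError("distance matrix not symmetric")
        if not np.allclose(np.diag(m), 0):
            raise ValueError("distance matrix diagonal not zero")
        if (m < 0).any():
            raise ValueError("negative distances")
        self.matrix = m


def distance(alignment: Alignment, model: str = "poisson") -> DistanceMatrix:
    """Pairwise distances with pairwise deletion of gapped columns.

    ``model="p"`` gives the proportion of mismatching compared columns;
    ``model="poisson"`` applies d = -ln(1 - p) (undefined at p = 1).
    """
    if model not in ("p", "poisson"):
        raise ValueError(f"unknown distance model {model!r}")
    rows = alignment.rows
    n = len(rows)
    if n < 2:
        raise ValueError("need >= 2 rows")
    arrs = [np.frombuffer(r.encode(), dtype="S1") for r in rows]
    gap = np.bytes_("-")
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ok = (arrs[i] != gap) & (arrs[j] != gap)
            compared = int(ok.sum())
            if compared == 0:
                raise ValueError(
                    f"no comparable columns between {alignment.ids[i]} and {alignment.ids[j]}"
                )
            p = float((arrs[i][ok] != arrs[j][ok]).sum()) / compared
            if model == "p":
                dij = p
            else:
                if p >= 1.0:
                    raise ValueError("poisson distance undefined at p = 1")
                dij = -math.log(1.0 - p)
            d[i, j] = d[j, i] = dij
    return DistanceMatrix(list(alignment.ids), d)


# ---------------------------------------------------------------------------
# Neighbor joining
# ---------------------------------------------------------------------------

def _nj_join_order(m: np.ndarray):
    """Sequence of index pairs NJ would join (indices into a growing list)."""
    n0 = m.shape[0]
    active = list(range(n0))
    mats = {(i, j): m[i, j] for i in range(n0) for j in range(n0)}

    def dist(i, j):
        return mats[(i, j)] if (i, j) in mats else mats[(j, i)]

    joins = []
    nxt = n0
    while len(active) > 3:
        n = len(active)
        r = {i: sum(dist(i, k) for k in active if k != i) for i in active}
        best = None
        for ai in range(n):
            for aj in range(ai + 1, n):
                i, j = active[ai], active[aj]
                q = (n - 2) * dist(i, j) - r[i] - r[j]
                if best is None or q < best[0] - 1e-12:
                    best = (q, i, j)
        _, i, j = best
        joins.append((i, j))
        for k in active:
            if k not in (i, j):
                mats[(nxt, k)] = 0.5 * (dist(i, k) + dist(j, k) - dist(i, j))
        active = [a for a in active if a not in (i, j)] + [nxt]
        nxt += 1
    if len(active) == 3:
        joins.append((active[0], active[1]))
    return joins


def neighbor_joining(dm: DistanceMatrix) -> dendropy.Tree:
    """Saitou-Nei neighbor joining.

    Ties on the Q criterion break by the smallest (i, j) index pair in the
    input order; negative branch-length estimates are clamped to zero with a
    warning.  Returns an unrooted :class:`dendropy.Tree`.
    """
    n0 = len(dm.ids)
    if n0 < 3:
        raise ValueError("neighbor joining needs >= 3 taxa")
    taxa = dendropy.TaxonNamespace(dm.ids)
    tree = dendropy.Tree(taxon_namespace=taxa)
    tree.is_rooted = False

    nodes = {}
    for idx, name in enumerate(dm.ids):
        node = dendropy.Node(taxon=taxa.get_taxon(name))
        nodes[idx] = node

    dmat = {}
    for i in range(n0):
        for j in range(i + 1, n0):
            dmat[(i, j)] = dm.matrix[i, j]

    def dist(i, j):
        if i == j:
            return 0.0
        return dmat[(i, j)] if i < j else dmat[(j, i)]

    def clamp(v, where):
        if v < 0:
            warnings.warn(f"negative NJ branch length {v:.4g} at {where}; clamped to 0")
            return 0.0
        return v

    active = list(range(n0))
    nxt = n0
    while len(active) > 3:
        n = len(active)
        r = {i: sum(dist(i, k) for k in active if k != i) for i in active}
        best = None
        for ai in range(n):
            for aj in range(ai + 1, n):
                i, j = active[ai], active[aj]
                q = (n - 2) * dist(i, j) - r[i] - r[j]
                if best is None or q < best[0] - 1e-12:
                    best = (q, i, j)
        _, i, j = best
        vi = clamp(0.5 * dist(i, j) + (r[i] - r[j]) / (2 * (n - 2)), f"join({i},{j})")
        vj = clamp(dist(i, j) - (0.5 * dist(i, j) + (r[i] - r[j]) / (2 * (n - 2))),
                   f"join({i},{j})")
        parent = dendropy.Node()
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        nodes[i].edge.length = vi
        nodes[j].edge.length = vj
        nodes[nxt] = parent
        for k in active:
            if k in (i, j):
                continue
            dnew = max(0.0, 0.5 * (dist(i, k) + dist(j, k) - dist(i, j)))
            key = (nxt, k) if nxt < k else (k, nxt)
            dmat[key] = dnew
        active = [a for a in active if a not in (i, j)] + [nxt]
        nxt += 1

    a, b, c = active
    va = clamp(0.5 * (dist(a, b) + dist(a, c) - dist(b, c)), "final")
    vb = clamp(0.5 * (dist(a, b) + dist(b, c) - dist(a, c)), "final")
    vc = clamp(0.5 * (dist(a, c) + dist(b, c) - dist(a, b)), "final")
    root = dendropy.Node()
    for idx, v in ((a, va), (b, vb), (c, vc)):
        root.add_child(nodes[idx])
        nodes[idx].edge.length = v
    tree.seed_node = root
    tree.is_rooted = False
    return tree


# ---------------------------------------------------------------------------
# Bootstrap and clades
# ---------------------------------------------------------------------------

def _resample_alignment(alignment: Alignment, rng) -> Alignment:
    ncol = len(alignment)
    idx = rng.integers(0, ncol, size=ncol)
    rows = ["".join(r[k] for k in idx) for r in alignment.rows]
    return Alignment(list(alignment.ids), rows)


def bootstrap_support(alignment: Alignment, n_reps: int = 100, seed: int = 0,
                      model: str = "poisson") -> dendropy.Tree:
    """NJ tree from the full alignment with column-bootstrap supports.

    Supports (round(100 * bipartition frequency)) are written as internal
    node labels.  A fully degenerate alignment (all rows identical) carries
    no phylogenetic signal: the tree is returned without supports.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    tree = neighbor_joining(distance(alignment, model))
    if len(set(alignment.rows)) == 1:
        return tree
    rng = np.random.default_rng(seed)
    taxa = tree.taxon_namespace
    counts: Counter = Counter()
    n_ok = 0
    for _ in range(n_reps):
        rep = _resample_alignment(alignment, rng)
        try:
            with warnings.catch_warnings():
                # replicate trees contribute topology only; branch-length
                # clamp warnings would repeat n_reps times
                warnings.simplefilter("ignore")
                rep_tree = neighbor_joining(distance(rep, model))
        except ValueError:
            warnings.warn("bootstrap replicate skipped (degenerate distances)")
            continue
        # re-map onto the reference taxon namespace for split comparison
        rep2 = dendropy.Tree.get(
            data=rep_tree.as_string(schema="newick"),
            schema="newick",
            taxon_namespace=taxa,
        )
        rep2.is_rooted = False
        rep2.encode_bipartitions()
        for bp in rep2.bipartition_encoding:
            counts[bp.split_bitmask] += 1
        n_ok += 1
    tree.encode_bipartitions()
    if n_ok:
        for node in tree.preorder_internal_node_iter(exclude_seed_node=True):
            freq = counts[node.edge.bipartition.split_bitmask] / n_ok
            node.label = str(round(100 * freq))
    return tree


@dataclass(frozen=True)
class CladeSupport:
    clade: frozenset
    support: int


def clades_at_support(tree: dendropy.Tree, min_support: float = 50,
                      min_size: int = 2) -> list[CladeSupport]:
    """Clades whose subtending bootstrap support meets ``min_support``.

    Every labelled internal edge is tested independently (nested qualifying
    clades are all reported).  Output is ordered by the lexicographic
    minimum of each clade's leaf set.
    """
    out = []
    for node in tree.preorder_internal_node_iter(exclude_seed_node=True):
        if node.label is None:
            continue
        support = int(node.label)
        leaves = frozenset(lf.taxon.label for lf in node.leaf_iter())
        if support >= min_support and len(leaves) >= min_size:
            out.append(CladeSupport(leaves, support))
    return sorted(out, key=lambda c: (min(c.clade), len(c.clade)))
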