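"""Alignment against a brute-force oracle, NJ against exhaustive
least-squares topology search and an independent library implementation,
and bootstrap/clade behaviour."""

import itertools
import math
import warnings

import numpy as np
import pytest
from Bio.Align import substitution_matrices

from mybkit.io_formats import SequenceRecord
from mybkit.phylo import (
    Alignment,
    DistanceMatrix,
    bootstrap_support,
    clades_at_support,
    distance,
    global_align,
    alignment_score,
    neighbor_joining,
    progressive_msa,
)

BLOSUM62 = substitution_matrices.load("BLOSUM62")
GO, GE = 10.0, 0.5


# ---------------------------------------------------------------------------
# Brute-force alignment oracle: enumerate every alignment as an op string.
# ---------------------------------------------------------------------------

def brute_force_best_score(a, b):
    best = -math.inf

    def score(ops):
        i = j = 0
        total = 0.0
        run = None
        for op in ops:
            if op == "M":
                total += BLOSUM62[a[i], b[j]]
                i += 1
                j += 1
                run = None
            else:
                total -= GE
                if run != op:
                    total -= GO
                run = op
            if op == "X":
                i += 1
            elif op == "Y":
                j += 1
        return total

    def rec(i, j, ops):
        nonlocal best
        if i == len(a) and j == len(b):
            best = max(best, score(ops))
            return
        if i < len(a) and j < len(b):
            rec(i + 1, j + 1, ops + "M")
        if i < len(a):
            rec(i + 1, j, ops + "X")
        if j < len(b):
            rec(i, j + 1, ops + "Y")

    rec(0, 0, "")
    return best


class TestGlobalAlign:
    def test_identical_sequences_align_without_gaps(self):
        aln, score = global_align("MK", "MK")
        assert aln.rows == ["MK", "MK"]
        assert score == BLOSUM62["M", "M"] + BLOSUM62["K", "K"]

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            global_align("A", "")

    def test_alphabet_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            global_align("ACGT", "MKWF")

    def test_matches_brute_force_enumeration(self, rng):
        """Optimal score equals exhaustive enumeration for short sequences."""
        aas = "ARNDCQEGHMK"
        for _ in range(15):
            la, lb = rng.integers(1, 6), rng.integers(1, 6)
            a = "".join(aas[i] for i in rng.integers(0, len(aas), la))
            b = "".join(aas[i] for i in rng.integers(0, len(aas), lb))
            _, score = global_align(a, b, gap_open=GO, gap_extend=GE)
            assert score == pytest.approx(brute_force_best_score(a, b)), (a, b)

    def test_score_agrees_with_biopython_aligner(self, rng):
        """Cross-check on longer sequences against Bio.Align.PairwiseAligner."""
        from Bio.Align import PairwiseAligner

        aligner = PairwiseAligner()
        aligner.substitution_matrix = BLOSUM62
        aligner.open_gap_score = -(GO + GE)
        aligner.extend_gap_score = -GE
        aligner.mode = "global"
        aas = "ACDEFGHIKLMNPQRSTVWY"
        for _ in range(5):
            a = "".join(aas[i] for i in rng.integers(0, 20, 40))
            b = "".join(aas[i] for i in rng.integers(0, 20, 35))
            assert alignment_score(a, b) == pytest.approx(aligner.score(a, b))

    def test_traceback_rows_ungap_to_inputs(self):
        aln, _ = global_align("MKVLWAAL", "MKWAL")
        assert aln.ungapped(0) == "MKVLWAAL"
        assert aln.ungapped(1) == "MKWAL"


class TestProgressiveMsa:
    def test_identical_sequences_gap_free(self):
        recs = [SequenceRecord("a", "MKVLW"), SequenceRecord("b", "MKVLW")]
        aln = progressive_msa(recs)
        assert aln.rows == ["MKVLW", "MKVLW"]

    def test_ungap_invariant(self, rng):
        aas = "ACDEFGHIKLMNPQRSTVWY"
        recs = [
            SequenceRecord(f"s{i}", "".join(
                aas[k] for k in rng.integers(0, 20, int(rng.integers(20, 30)))))
            for i in range(5)
        ]
        aln = progressive_msa(recs)
        for i, r in enumerate(recs):
            assert aln.ungapped(i) == r.sequence
        assert len(aln) >= max(len(r.sequence) for r in recs)

    def test_planted_repeat_columns_align(self, repeat_model, rng):
        """Homologous repeat residues (identical planted blocks separated by
        random spacers of different lengths) must land in shared columns for
        >= 95% of repeat positions."""
        consensus = "".join(
            "ACDEFGHIKLMNPQRSTVWY"[k]
            for k in np.argmax(repeat_model.frequencies, axis=1)
        )
        recs, spans = [], []
        for i in range(4):
            lens = [int(rng.integers(4, 12)) for _ in range(3)]
            seq = ("".join("ACDEFGHIKLMNPQRSTVWY"[k]
                           for k in rng.integers(0, 20, lens[0]))
                   + consensus
                   + "".join("ACDEFGHIKLMNPQRSTVWY"[k]
                             for k in rng.integers(0, 20, lens[1]))
                   + consensus
                   + "".join("ACDEFGHIKLMNPQRSTVWY"[k]
                             for k in rng.integers(0, 20, lens[2])))
            recs.append(SequenceRecord(f"s{i}", seq))
            spans.append([(lens[0], lens[0] + 52),
                          (lens[0] + 52 + lens[1], lens[0] + 104 + lens[1])])
        aln = progressive_msa(recs)
        col_of = []
        for row in aln.rows:
            mapping = [c for c, ch in enumerate(row) if ch != "-"]
            col_of.append(mapping)
        agree = total = 0
        for rep in range(2):
            for p in range(52):
                cols = {col_of[i][spans[i][rep][0] + p] for i in range(4)}
                total += 1
                agree += len(cols) == 1
        assert agree / total >= 0.95


class TestDistance:
    def test_identical_rows_zero(self):
        aln = Alignment(["a", "b"], ["MKVL", "MKVL"])
        assert distance(aln, "p").matrix[0, 1] == 0.0

    def test_p_distance_arithmetic(self):
        aln = Alignment(["a", "b"], ["AAAAAAAAAA", "AAAAAAAAAC"])
        assert distance(aln, "p").matrix[0, 1] == pytest.approx(0.1)

    def test_poisson_closed_form_and_dominance(self):
        aln = Alignment(["a", "b"], ["AAAAAAAAAA", "AAAAAAAAAC"])
        d = distance(aln, "poisson").matrix[0, 1]
        assert d == pytest.approx(-math.log(0.9))
        assert d >= distance(aln, "p").matrix[0, 1]

    def test_pairwise_deletion_of_gapped_columns(self):
        aln = Alignment(["a", "b"], ["MK-L", "MKVL"])
        assert distance(aln, "p").matrix[0, 1] == 0.0

    def test_poisson_undefined_at_saturation(self):
        aln = Alignment(["a", "b"], ["AAAA", "CCCC"])
        with pytest.raises(ValueError):
            distance(aln, "poisson")


# ---------------------------------------------------------------------------
# Exhaustive topology oracle
# ---------------------------------------------------------------------------

def enumerate_topologies(n):
    """All unrooted binary topologies on leaves 0..n-1 as edge lists."""
    trees = [[(0, -1), (1, -1), (2, -1)]]
    next_internal = -2
    for leaf in range(3, n):
        new_trees = []
        for edges in trees:
            for k, (u, v) in enumerate(edges):
                mid = next_internal
                new = [e for i, e in enumerate(edges) if i != k]
                new += [(u, mid), (v, mid), (leaf, mid)]
                new_trees.append(new)
        trees = new_trees
        next_internal -= 1
    return trees


def tree_bipartitions(edges, n):
    """Nontrivial splits as frozensets of the side not containing leaf 0."""
    import networkx as nx

    g = nx.Graph(edges)
    splits = set()
    for u, v in edges:
        g.remove_edge(u, v)
        side = {x for x in nx.node_connected_component(g, u) if x >= 0}
        g.add_edge(u, v)
        if 0 in side:
            side = {x for x in range(n)} - side
        if 2 <= len(side) <= n - 2:
            splits.add(frozenset(side))
    return splits


def ls_residual(edges, n, D):
    """Least-squares fit of branch lengths to D for one topology."""
    import networkx as nx

    g = nx.Graph()
    for k, (u, v) in enumerate(edges):
        g.add_edge(u, v, idx=k)
    rows, y = [], []
    for i in range(n):
        for j in range(i + 1, n):
            path = nx.shortest_path(g, i, j)
            row = np.zeros(len(edges))
            for u, v in zip(path, path[1:]):
                row[g[u][v]["idx"]] = 1.0
            rows.append(row)
            y.append(D[i, j])
    A = np.array(rows)
    sol, *_ = np.linalg.lstsq(A, np.array(y), rcond=None)
    return float(((A @ sol - np.array(y)) ** 2).sum())


def random_additive_instance(rng, n):
    """A random binary tree and its exact leaf-to-leaf distance matrix."""
    import networkx as nx

    edges = [(0, -1), (1, -1), (2, -1)]
    next_internal = -2
    for leaf in range(3, n):
        k = int(rng.integers(len(edges)))
        u, v = edges.pop(k)
        mid = next_internal
        next_internal -= 1
        edges += [(u, mid), (v, mid), (leaf, mid)]
    g = nx.Graph()
    for u, v in edges:
        g.add_edge(u, v, weight=float(rng.uniform(0.2, 1.0)))
    D = np.zeros((n, n))
    for i in range(n):
        lengths = nx.single_source_dijkstra_path_length(g, i)
        for j in range(n):
            D[i, j] = lengths[j]
    np.fill_diagonal(D, 0.0)
    return edges, (D + D.T) / 2


def nj_bipartitions(tree, ids):
    index = {name: k for k, name in enumerate(ids)}
    n = len(ids)
    splits = set()
    for node in tree.preorder_internal_node_iter(exclude_seed_node=True):
        side = frozenset(index[lf.taxon.label] for lf in node.leaf_iter())
        if 0 in side:
            side = frozenset(range(n)) - side
        if 2 <= len(side) <= n - 2:
            splits.add(side)
    return splits


class TestNeighborJoining:
    def test_recovers_every_random_additive_topology_n4_to_n6(self, rng):
        """NJ output topology equals both the generating tree and the
        winner of exhaustive least-squares topology search."""
        for n in (4, 5, 6):
            for _ in range(3):
                true_edges, D = random_additive_instance(rng, n)
                ids = [f"t{i}" for i in range(n)]
                tree = neighbor_joining(DistanceMatrix(ids, D))
                got = nj_bipartitions(tree, ids)
                want = tree_bipartitions(true_edges, n)
                assert got == want, (n, D)
                best = min(
                    enumerate_topologies(n),
                    key=lambda e: ls_residual(e, n, D),
                )
                assert tree_bipartitions(best, n) == want

    def test_three_taxon_closed_form(self):
        D = np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], float)
        tree = neighbor_joining(DistanceMatrix(["a", "b", "c"], D))
        lengths = {
            lf.taxon.label: lf.edge.length for lf in tree.leaf_node_iter()
        }
        assert lengths == pytest.approx({"a": 1.0, "b": 2.0, "c": 3.0})

    def test_topology_invariant_under_taxon_permutation(self, rng):
        _, D = random_additive_instance(rng, 6)
        ids = [f"t{i}" for i in range(6)]
        tree1 = neighbor_joining(DistanceMatrix(ids, D))
        perm = rng.permutation(6)
        D2 = D[np.ix_(perm, perm)]
        ids2 = [ids[k] for k in perm]
        tree2 = neighbor_joining(DistanceMatrix(ids2, D2))
        def named_splits(tree):
            out = set()
            for node in tree.preorder_internal_node_iter(exclude_seed_node=True):
                s = frozenset(lf.taxon.label for lf in node.leaf_iter())
                if "t0" in s:
                    s = frozenset(ids) - s
                if 2 <= len(s) <= 4:
                    out.add(s)
            return out
        assert named_splits(tree1) == named_splits(tree2)

    def test_agrees_with_scikit_bio(self, rng):
        """Independent-implementation cross-check on an additive matrix."""
        import skbio
        from skbio.tree import nj as skbio_nj

        _, D = random_additive_instance(rng, 6)
        ids = [f"t{i}" for i in range(6)]
        mine = neighbor_joining(DistanceMatrix(ids, D))
        theirs = skbio_nj(skbio.DistanceMatrix(D, ids))
        their_splits = set()
        for node in theirs.non_tips():
            s = frozenset(t.name for t in node.tips())
            if "t0" in s:
                s = frozenset(ids) - s
            if 2 <= len(s) <= 4:
                their_splits.add(s)
        my_splits = set()
        for node in mine.preorder_internal_node_iter(exclude_seed_node=True):
            s = frozenset(lf.taxon.label for lf in node.leaf_iter())
            if "t0" in s:
                s = frozenset(ids) - s
            if 2 <= len(s) <= 4:
                my_splits.add(s)
        assert my_splits == their_splits

    def test_negative_branch_clamped_with_warning(self):
        D = np.array(
            [
                [0.0, 2.575, 1.895, 1.03],
                [2.575, 0.0, 1.74, 0.61],
                [1.895, 1.74, 0.0, 0.305],
                [1.03, 0.61, 0.305, 0.0],
            ]
        )
        with pytest.warns(UserWarning, match="clamped"):
            tree = neighbor_joining(DistanceMatrix(list("abcd"), D))
        for edge in tree.preorder_edge_iter():
            if edge.length is not None:
                assert edge.length >= 0


def _two_clade_alignment(rng, n_per_clade=3, length=120, within=3, between=60):
    aas = "ACDEFGHIKLMNPQRSTVWY"

    def mutate(s, k):
        s = list(s)
        for p in rng.choice(len(s), size=k, replace=False):
            s[p] = aas[rng.integers(20)]
        return "".join(s)

    base1 = "".join(aas[i] for i in rng.integers(0, 20, length))
    base2 = mutate(base1, between)
    rows = [mutate(base1, within) for _ in range(n_per_clade)]
    rows += [mutate(base2, within) for _ in range(n_per_clade)]
    ids = [f"a{i}" for i in range(n_per_clade)] + [
        f"b{i}" for i in range(n_per_clade)
    ]
    return Alignment(ids, rows)


class TestBootstrap:
    def test_same_seed_identical_supports(self, rng):
        aln = _two_clade_alignment(rng)
        t1 = bootstrap_support(aln, n_reps=30, seed=9)
        t2 = bootstrap_support(aln, n_reps=30, seed=9)
        assert t1.as_string(schema="newick") == t2.as_string(schema="newick")

    def test_identical_sequences_have_no_supports(self):
        aln = Alignment(["a", "b", "c"], ["MKVL"] * 3)
        tree = bootstrap_support(aln, n_reps=10, seed=0)
        labels = [n.label for n in tree.preorder_internal_node_iter()]
        assert all(lb is None for lb in labels)

    def test_separating_bipartition_strongly_supported(self, rng):
        aln = _two_clade_alignment(rng)
        tree = bootstrap_support(aln, n_reps=100, seed=4)
        clades = clades_at_support(tree, 95)
        wanted = [
            c for c in clades
            if c.clade in ({"a0", "a1", "a2"}, {"b0", "b1", "b2"})
        ]
        assert wanted and all(c.support >= 95 for c in wanted)


class TestCladesAtSupport:
    def _tree(self):
        import dendropy

        return dendropy.Tree.get(
            data="(((a:1,b:1)80:1,(c:1,d:1)60:1)40:1,(e:1,f:1):1,g:1);",
            schema="newick",
        )

    def test_threshold_zero_yields_every_labelled_edge(self):
        clades = clades_at_support(self._tree(), 0)
        assert {c.support for c in clades} == {40, 60, 80}

    def test_threshold_above_100_yields_nothing(self):
        assert clades_at_support(self._tree(), 101) == []

    def test_hand_built_supports_filtered_at_50(self):
        clades = clades_at_support(self._tree(), 50)
        got = {(frozenset(c.clade), c.support) for c in clades}
        assert got == {
            (frozenset({"a", "b"}), 80),
            (frozenset({"c", "d"}), 60),
        }

    def test_ordering_is_deterministic(self):
        clades = clades_at_support(self._tree(), 0)
        keys = [min(c.clade) for c in clades]
        assert keys == sorted(keys)
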