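"""Expression quantification and the PCC co-expression network.

Quantification: RPKM (reads per kilobase of exon model per million mapped
reads) for RNA-seq counts and the 2^-ddCt method for qPCR.  Genes are
flagged highly expressed when RPKM exceeds 10 in at least one stage and
lowly expressed when RPKM falls below 1 in more than two stages; responder
sets use a fold-change bound of 2 (reciprocal bound 1/2 for repression).
The co-expression network links genes whose Pearson correlation (on
log2(x+1)-transformed values by default) meets the 0.85 cutoff, and hubs
are nodes with strictly more than 12 connections.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage

from .io_formats import ExpressionMatrix

PCC_CUTOFF = 0.85
HUB_DEGREE = 12
FOLD_THRESHOLD = 2.0
HIGH_RPKM = 10.0
LOW_RPKM = 1.0


def rpkm(counts: ExpressionMatrix | pd.DataFrame, gene_lengths_bp: pd.Series,
         total_mapped: pd.Series | None = None) -> ExpressionMatrix:
    """RPKM = count / (gene length in kb * mapped reads in millions).

    ``total_mapped`` defaults to each sample's column sum.
    """
    df = counts.values if isinstance(counts, ExpressionMatrix) else counts
    lengths = gene_lengths_bp.reindex(df.index)
    if lengths.isna().any():
        missing = list(lengths.index[lengths.isna()])[:3]
        raise ValueError(f"missing gene lengths, e.g. {missing}")
    if (lengths <= 0).any():
        raise ValueError("gene lengths must be positive")
    if total_mapped is None:
        total_mapped = df.sum(axis=0)
    total_mapped = total_mapped.reindex(df.columns)
    if (total_mapped <= 0).any():
        raise ValueError("total mapped reads must be positive per sample")
    out = df.div(lengths / 1e3, axis=0).div(total_mapped / 1e6, axis=1)
    return ExpressionMatrix(out, units="RPKM")


def expression_groups(matrix: ExpressionMatrix, high: float = HIGH_RPKM,
                      low: float = LOW_RPKM, n_clusters: int = 4) -> pd.DataFrame:
    """Threshold flags plus a 4-group profile clustering.

    ``high_any`` is true when the gene exceeds ``high`` in at least one
    stage; ``low_most`` when it falls below ``low`` in more than two stages.
    Profiles (row-standardized) are clustered by average linkage on 1 - PCC
    distance, cut at ``n_clusters`` groups (I..IV by default).
    """
    df = matrix.values
    if df.shape[1] < 4:
        raise ValueError("profile clustering needs >= 4 samples")
    flags = pd.DataFrame(
        {
            "high_any": (df > high).any(axis=1),
            "low_most": (df < low).sum(axis=1) > 2,
        },
        index=df.index,
    )
    std = df.std(axis=1, ddof=0)
    usable = std > 0
    groups = pd.Series(0, index=df.index, dtype=int)
    if usable.sum() >= n_clusters:
        z = df.loc[usable]
        link = linkage(z.values, method="average", metric="correlation")
        labels = fcluster(link, t=n_clusters, criterion="maxclust")
        groups.loc[usable] = labels
    roman = {0: "", 1: "I", 2: "II", 3: "III", 4: "IV"}
    flags["group"] = groups.map(lambda k: roman.get(k, str(k)))
    return flags


# ---------------------------------------------------------------------------
# qPCR relative quantification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class QpcrResult:
    sample_id: str
    gene_id: str
    delta_ct: float
    delta_delta_ct: float
    fold_change: float


def ddct(ct_table: pd.DataFrame, reference_gene: str,
         calibrator_sample: str) -> pd.DataFrame:
    """Relative expression by the 2^-ddCt method.

    Replicate Cts are averaged; dCt = Ct_target - Ct_reference per sample;
    ddCt subtracts the calibrator sample's dCt; fold change = 2^-ddCt (the
    calibrator's fold change is exactly 1 by construction).
    """
    mean_ct = (
        ct_table.groupby(["sample_id", "gene_id"])["ct"].mean().unstack()
    )
    if reference_gene not in mean_ct.columns:
        raise ValueError(f"reference gene {reference_gene!r} absent from table")
    missing = mean_ct.index[mean_ct[reference_gene].isna()]
    if len(missing):
        raise ValueError(
            f"reference gene {reference_gene!r} missing in sample {missing[0]!r}"
        )
    if calibrator_sample not in mean_ct.index:
        raise ValueError(f"calibrator sample {calibrator_sample!r} absent")
    dct = mean_ct.sub(mean_ct[reference_gene], axis=0).drop(columns=reference_gene)
    ddct_ = dct.sub(dct.loc[calibrator_sample], axis=1)
    rows = []
    for sample in dct.index:
        for gene in dct.columns:
            if math.isnan(dct.loc[sample, gene]):
                continue
            d2 = ddct_.loc[sample, gene]
            rows.append(
                QpcrResult(sample, gene, dct.loc[sample, gene], d2, 2.0 ** (-d2))
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Responder sets and Venn intersections
# ---------------------------------------------------------------------------

@dataclass
class ResponderSet:
    treatment: str
    up: set
    down: set
    threshold: float = FOLD_THRESHOLD

    def __post_init__(self):
        if self.up & self.down:
            raise ValueError("up and down responder sets must be disjoint")


def responder_sets(fold_changes: dict[str, pd.DataFrame],
                   threshold: float = FOLD_THRESHOLD) -> list[ResponderSet]:
    """Per-treatment up/down responder sets from fold-change tables.

    ``fold_changes`` maps each treatment to a genes x timepoints table of
    fold changes relative to that treatment's time 0.  A gene is up when its
    maximum fold is >= threshold and down when its minimum is <= 1/threshold;
    the rare gene satisfying both is assigned to the direction with the
    larger |log2 fold| excursion (the sets are disjoint by contract).
    """
    out = []
    for treatment, folds in fold_changes.items():
        if (folds.values <= 0).any():
            raise ValueError(f"non-positive fold change under {treatment!r}")
        up, down = set(), set()
        for gene, row in folds.iterrows():
            hi, lo = row.max(), row.min()
            is_up = hi >= threshold
            is_down = lo <= 1.0 / threshold
            if is_up and is_down:
                if abs(np.log2(hi)) >= abs(np.log2(lo)):
                    is_down = False
                else:
                    is_up = False
            if is_up:
                up.add(gene)
            elif is_down:
                down.add(gene)
        out.append(ResponderSet(treatment, up, down, threshold))
    return out


def venn_counts(sets: dict[str, set]) -> pd.DataFrame:
    """Exclusive intersection counts for all 2^k - 1 membership patterns.

    The cells partition the union: each element is counted once, in the cell
    of exactly the sets containing it.
    """
    names = list(sets)
    rows = []
    for r in range(1, len(names) + 1):
        for combo in itertools.combinations(names, r):
            inside = set.intersection(*(sets[n] for n in combo))
            outside = set.union(set(), *(sets[n] for n in names if n not in combo))
            exclusive = inside - outside
            rows.append(
                {"sets": "&".join(combo), "count": len(exclusive)}
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Co-expression network
# ---------------------------------------------------------------------------

def pcc(x, y) -> float:
    """Pearson product-moment correlation of two equal-length vectors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("pcc needs two equal-length vectors")
    if len(x) < 3:
        raise ValueError("pcc needs length >= 3")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("pcc undefined for a constant vector")
    return float(np.corrcoef(x, y)[0, 1])


@dataclass
class CoexpressionNetwork:
    graph: nx.Graph
    cutoff: float
    hub_k: int = HUB_DEGREE

    @property
    def edges(self):
        return [
            (min(u, v), max(u, v), d["pcc"])
            for u, v, d in self.graph.edges(data=True)
        ]

    @property
    def hubs(self) -> set:
        return find_hubs(self, self.hub_k)


def build_network(matrix: ExpressionMatrix | pd.DataFrame,
                  cutoff: float = PCC_CUTOFF, log_transform: bool = True,
                  absolute: bool = False, hub_k: int = HUB_DEGREE
                  ) -> CoexpressionNetwork:
    """PCC co-expression network at a correlation cutoff.

    Values are log2(x+1)-transformed by default.  Edges require
    pcc >= cutoff (positive co-expression, as displayed in this family's
    published network); ``absolute=True`` opts into |pcc| >= cutoff.
    Zero-variance genes are excluded with a warning.
    """
    df = matrix.values if isinstance(matrix, ExpressionMatrix) else matrix
    if df.shape[1] < 3:
        raise ValueError("network construction needs >= 3 samples")
    if df.shape[0] < 2:
        raise ValueError("network construction needs >= 2 genes")
    data = np.log2(df + 1.0) if log_transform else df.copy()
    std = data.std(axis=1, ddof=0)
    dropped = list(std.index[std == 0])
    if dropped:
        warnings.warn(f"excluding zero-variance genes: {dropped}")
        data = data.loc[std > 0]
    genes = list(data.index)
    corr = np.corrcoef(data.values)
    graph = nx.Graph()
    graph.add_nodes_from(genes)
    for i in range(len(genes)):
        for j in range(i + 1, len(genes)):
            c = corr[i, j]
            keep = abs(c) >= cutoff if absolute else c >= cutoff
            if keep:
                graph.add_edge(genes[i], genes[j], pcc=float(c))
    return CoexpressionNetwork(graph, cutoff, hub_k)


def find_hubs(net: CoexpressionNetwork, k: int = HUB_DEGREE) -> set:
    """Hub genes: nodes with strictly more than ``k`` connections."""
    return {n for n, d in net.graph.degree() if d > k}
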