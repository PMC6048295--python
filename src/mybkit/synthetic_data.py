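"""Synthetic inputs with known ground truth for every pipeline stage.

Every generator is a deterministic function of its config and seed, and
returns the truth needed to score the downstream stage exactly:

* :func:`simulate_codon_pair` — a CDS pair diverged by fate-labelled
  substitution events (realized synonymous/nonsynonymous counts recorded);
* :func:`plant_myb_protein` — proteins with planted ~52-aa MYB repeats at
  known spans;
* :func:`simulate_gene_model` — gene models whose introns sit at requested
  codon positions and phases, on either strand;
* :func:`simulate_expression` — expression matrices with planted correlated
  modules and planted fold-change responders;
* :func:`simulate_ct_table` — qPCR Ct tables with a known delta-delta-Ct
  grid.

The substitution simulator works codon-wise with explicit fate labelling
(rather than a rate-matrix CTMC) so realized truth counts are exact, and
stop codons are forbidden by rejection, which keeps the counting rules of
the estimator unambiguous on the truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import ExpressionMatrix, GeneModel, SequenceRecord
from .molevol import (
    BASES,
    STOP_CODONS,
    codon_neighbors,
    synonymous_fraction,
)

SENSE_CODONS = tuple(
    a + b + c
    for a in BASES
    for b in BASES
    for c in BASES
    if a + b + c not in STOP_CODONS
)


# ---------------------------------------------------------------------------
# Codon-pair divergence
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FamilySimConfig:
    """Divergence-simulation settings for one CDS pair.

    ``target_ks`` is the expected number of synonymous substitutions per
    synonymous site between the two sequences (and ``target_ks *
    ka_ks_ratio`` the nonsynonymous analogue); values in the range the
    family's recent paralogs show (Ks roughly 0.07-0.19) date pairs to the
    last ~5-15 million years under the grass clock.
    """

    n_genes: int = 1
    n_codons: int = 300
    target_ks: float = 0.15
    ka_ks_ratio: float = 0.7
    transition_bias: float = 0.0  # reserved; 0 = no bias
    seed: int = 0

    def __post_init__(self):
        if self.target_ks < 0 or self.ka_ks_ratio < 0:
            raise ValueError("target_ks and ka_ks_ratio must be >= 0")
        if self.n_codons < 10:
            raise ValueError("n_codons must be >= 10")


def random_cds(rng: np.random.Generator, n_codons: int) -> str:
    """Random in-frame CDS: ATG start, no stop codons."""
    body = rng.choice(len(SENSE_CODONS), size=n_codons - 1)
    return "ATG" + "".join(SENSE_CODONS[i] for i in body)


def _apply_events(rng, codons: list[str], n_events: int, synonymous: bool) -> int:
    """Apply fate-labelled single-nucleotide substitutions in place."""
    applied = 0
    for _ in range(n_events):
        for _attempt in range(10_000):
            i = int(rng.integers(len(codons)))
            options = [
                (pos, alt) for pos, alt, syn in codon_neighbors(codons[i])
                if syn == synonymous
            ]
            if options:
                pos, alt = options[int(rng.integers(len(options)))]
                codons[i] = alt
                applied += 1
                break
        else:
            raise ValueError(
                "infeasible config: no codon admits a "
                f"{'synonymous' if synonymous else 'nonsynonymous'} change"
            )
    return applied


def simulate_codon_pair(config: FamilySimConfig,
                        rng: np.random.Generator | None = None):
    """Simulate one diverged CDS pair with exact realized truth counts.

    Sequence b derives from a by Poisson(target_ks * S) synonymous and
    Poisson(target_ka * N) nonsynonymous single-nucleotide events, where S
    and N are the NG86 site counts of the starting sequence; each event
    picks a codon uniformly among those admitting a change of its fate and
    then one such change uniformly.  Stop codons are never created.
    Returns (record_a, record_b, truth) with truth = {"syn_events",
    "nonsyn_events", "S", "N"}.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    cds_a = random_cds(rng, config.n_codons)
    codons = [cds_a[i:i + 3] for i in range(0, len(cds_a), 3)]
    S = sum(synonymous_fraction(c) for c in codons)
    N = 3.0 * len(codons) - S
    target_ka = config.target_ks * config.ka_ks_ratio
    n_syn = int(rng.poisson(config.target_ks * S)) if config.target_ks > 0 else 0
    n_non = int(rng.poisson(target_ka * N)) if target_ka > 0 else 0
    ns = _apply_events(rng, codons, n_syn, synonymous=True)
    nn = _apply_events(rng, codons, n_non, synonymous=False)
    cds_b = "".join(codons)
    truth = {"syn_events": ns, "nonsyn_events": nn, "S": S, "N": N}
    return (
        SequenceRecord("pair_a", cds_a),
        SequenceRecord("pair_b", cds_b),
        truth,
    )


# ---------------------------------------------------------------------------
# Proteins with planted MYB repeats
# ---------------------------------------------------------------------------

def _sample_repeat(rng, model) -> str:
    """Draw a repeat from the model's column frequencies, rejecting the rare
    draw that would score below threshold (keeps scanner recall exact)."""
    from .family_scan import AMINO_ACIDS

    landmarks = set(model.landmark_positions)
    for _ in range(1000):
        residues = [
            "W" if c in landmarks
            else AMINO_ACIDS[rng.choice(20, p=model.frequencies[c])]
            for c in range(model.length)
        ]
        block = "".join(residues)
        if model.window_score(block) >= model.score_threshold:
            return block
    raise RuntimeError("could not sample a scoring repeat block")


def _random_spacer(rng, length: int) -> str:
    from .family_scan import AMINO_ACIDS

    return "".join(AMINO_ACIDS[i] for i in rng.choice(20, size=length))


def plant_myb_protein(n_repeats: int, spacer_len: int = 20, seed: int = 0,
                      model=None, record_id: str = "planted"):
    """Protein with ``n_repeats`` planted MYB repeats at known spans.

    Repeats are separated (and flanked) by uniform-random spacers of
    ``spacer_len`` residues.  Returns (SequenceRecord, truth_spans) where
    truth_spans is a list of 0-based half-open (start, end) tuples.
    """
    if not 0 <= n_repeats <= 4:
        raise ValueError("n_repeats must be in 0..4")
    if model is None:
        from .family_scan import default_repeat_model

        model = default_repeat_model()
    rng = np.random.default_rng(seed)
    pieces = [_random_spacer(rng, spacer_len)]
    spans = []
    pos = spacer_len
    for _ in range(n_repeats):
        block = _sample_repeat(rng, model)
        pieces.append(block)
        spans.append((pos, pos + model.length))
        pos += model.length
        spacer = _random_spacer(rng, spacer_len)
        pieces.append(spacer)
        pos += spacer_len
    return SequenceRecord(record_id, "".join(pieces)), spans


def myb_family_records(n_genes: int, n_repeats: int = 2, spacer_len: int = 20,
                       seed: int = 0, model=None):
    """A small family of planted-repeat proteins (independent spacers)."""
    out = []
    for k in range(n_genes):
        rec, spans = plant_myb_protein(
            n_repeats, spacer_len, seed=seed + k, model=model,
            record_id=f"gene{k + 1}",
        )
        out.append((rec, spans))
    return out


# ---------------------------------------------------------------------------
# Gene models with introns at known phases
# ---------------------------------------------------------------------------

def simulate_gene_model(intron_spec, n_codons: int | None = None,
                        gene_id: str = "simgene", seq_id: str = "chr_sim",
                        strand: str = "+", intron_len: int = 120,
                        offset: int = 1000) -> GeneModel:
    """Gene model whose CDS-interrupting introns sit at the requested
    (codon_index, phase) positions.

    ``intron_spec`` lists (codon_index, phase) with phase in {0,1,2}: the
    intron is inserted after coding nucleotide 3*codon_index + phase.  The
    model is single-mRNA, CDS == exons (no UTR), placed at ``offset`` on a
    synthetic contig; on the minus strand the genomic layout is mirrored but
    the transcription-order phases are identical.
    """
    spec = sorted(intron_spec)
    for codon_index, phase in spec:
        if phase not in (0, 1, 2):
            raise ValueError(f"bad phase {phase}")
        if codon_index < 1:
            raise ValueError("codon_index must be >= 1")
    cuts = [3 * ci + ph for ci, ph in spec]
    if len(set(cuts)) != len(cuts):
        raise ValueError("duplicate intron positions")
    if n_codons is None:
        n_codons = (max((ci for ci, _ in spec), default=5)) + 5
    cds_len = 3 * n_codons
    if cuts and max(cuts) >= cds_len:
        raise ValueError("intron position beyond CDS end")
    # split CDS into pieces at the cut offsets (transcript coordinates)
    bounds = [0] + cuts + [cds_len]
    piece_lens = [b2 - b1 for b1, b2 in zip(bounds, bounds[1:])]
    exons_txn = []  # (start, end) in transcript-forward genomic terms
    cursor = offset
    for k, plen in enumerate(piece_lens):
        exons_txn.append((cursor, cursor + plen))
        cursor += plen
        if k < len(piece_lens) - 1:
            cursor += intron_len
    if strand == "-":
        total = cursor - offset
        # mirror: transcript-forward coordinate x -> genomic offset+total-x
        mirrored = [
            (offset + (total - (e - offset)), offset + (total - (s - offset)))
            for s, e in exons_txn
        ]
        exons = mirrored  # already in transcription order (high -> low)
    else:
        exons = exons_txn
    return GeneModel(
        gene_id=gene_id, seq_id=seq_id, strand=strand,
        exons=exons, cds=[tuple(x) for x in exons],
    )


def random_intron_spec(rng: np.random.Generator, max_introns: int = 4,
                       n_codons: int = 40):
    """Random (codon_index, phase) list for round-trip phase tests."""
    n = int(rng.integers(0, max_introns + 1))
    cuts = set()
    while len(cuts) < n:
        ci = int(rng.integers(1, n_codons - 1))
        ph = int(rng.integers(0, 3))
        cuts.add((ci, ph))
    spec = sorted(cuts)
    # distinct coding offsets required
    offsets = [3 * ci + ph for ci, ph in spec]
    if len(set(offsets)) != len(offsets):
        return random_intron_spec(rng, max_introns, n_codons)
    return spec


# ---------------------------------------------------------------------------
# Expression matrices with planted modules and responders
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ExprSimConfig:
    """Planted-module expression simulation.

    Module genes share a latent per-sample profile with correlation
    ``within_module_rho`` on the log2 scale; ``noise_sd`` adds measurement
    noise.  ``responder_fraction`` of genes receive a ``log2fc_effect``
    shift in the treated half of the samples (truth-flagged).
    """

    n_genes: int = 60
    n_samples: int = 12
    n_modules: int = 3
    module_size: int = 10
    within_module_rho: float = 0.95
    noise_sd: float = 0.1
    responder_fraction: float = 0.0
    log2fc_effect: float = 0.0
    baseline_log2: float = 5.0
    seed: int = 0

    def __post_init__(self):
        if not 0 <= self.within_module_rho <= 1:
            raise ValueError("within_module_rho must be in [0,1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.n_modules * self.module_size > self.n_genes:
            raise ValueError("module sizes exceed gene count")
        if not 0 <= self.responder_fraction <= 1:
            raise ValueError("responder_fraction must be in [0,1]")


def simulate_expression(config: ExprSimConfig):
    """Expression matrix with planted co-expression modules and responders.

    Log2 expression of a module gene g in sample s is
    ``baseline + sqrt(rho) * f_m(s) + a * e + noise_sd * n`` with f_m the
    module's latent N(0,1) profile and ``a = sqrt(1 - rho - noise_sd**2)``
    (clamped at 0), so the population correlation between two genes of one
    module equals ``within_module_rho`` exactly — measurement noise is part
    of the idiosyncratic variance, not added on top.  Background genes are
    baseline plus unit noise; the matrix holds 2**log2 values (RPKM scale).
    Responders additionally gain ``log2fc_effect`` in the second half of the
    samples.  Returns (ExpressionMatrix, truth) with truth a DataFrame
    (gene_id, module, responder).
    """
    rng = np.random.default_rng(config.seed)
    genes = [f"g{i + 1:03d}" for i in range(config.n_genes)]
    samples = [f"s{j + 1:02d}" for j in range(config.n_samples)]
    rho = config.within_module_rho
    idio_sd = math.sqrt(max(1.0 - rho - config.noise_sd ** 2, 0.0))
    log2x = np.zeros((config.n_genes, config.n_samples))
    module_of = np.full(config.n_genes, -1)
    latent = rng.normal(size=(config.n_modules, config.n_samples))
    g = 0
    for m in range(config.n_modules):
        for _ in range(config.module_size):
            module_of[g] = m
            log2x[g] = (
                np.sqrt(rho) * latent[m]
                + idio_sd * rng.normal(size=config.n_samples)
            )
            g += 1
    for gg in range(g, config.n_genes):
        log2x[gg] = rng.normal(size=config.n_samples)
    log2x += config.noise_sd * rng.normal(size=log2x.shape)
    log2x += config.baseline_log2
    n_resp = int(round(config.responder_fraction * config.n_genes))
    responders = rng.choice(config.n_genes, size=n_resp, replace=False)
    treated = np.arange(config.n_samples) >= config.n_samples // 2
    for gg in responders:
        log2x[gg, treated] += config.log2fc_effect
    values = pd.DataFrame(2.0 ** log2x, index=genes, columns=samples)
    truth = pd.DataFrame(
        {
            "gene_id": genes,
            "module": module_of,
            "responder": np.isin(np.arange(config.n_genes), responders),
        }
    )
    return ExpressionMatrix(values, units="RPKM"), truth


def true_module_edges(truth: pd.DataFrame) -> set[frozenset]:
    """All within-module gene pairs (the planted co-expression edges)."""
    edges = set()
    for _, grp in truth[truth["module"] >= 0].groupby("module"):
        ids = list(grp["gene_id"])
        for i in range(len(ids)):
            for j in range(i + 1, len(ids)):
                edges.add(frozenset((ids[i], ids[j])))
    return edges


# ---------------------------------------------------------------------------
# qPCR Ct tables with a known delta-delta-Ct grid
# ---------------------------------------------------------------------------

def simulate_ct_table(effects: pd.DataFrame, seed: int = 0,
                      reference_gene: str = "TIP41",
                      calibrator_sample: str | None = None,
                      n_replicates: int = 3, noise_sd: float = 0.0,
                      base_ct: float = 24.0, ref_ct: float = 20.0):
    """Ct table realizing a requested delta-delta-Ct grid.

    ``effects`` is a genes x samples DataFrame of true ddCt values (the
    calibrator column, by default the first, must be 0).  Per-sample
    loading shifts are added to both reference and targets so the ddCt
    structure survives them.  Returns (ct_table, truth) with the table in
    the long Ct format and truth the input grid.
    """
    rng = np.random.default_rng(seed)
    samples = list(effects.columns)
    calibrator_sample = calibrator_sample or samples[0]
    if not np.allclose(effects[calibrator_sample], 0):
        raise ValueError("calibrator column of the ddCt grid must be zero")
    load = {s: rng.normal(scale=0.3) for s in samples}
    rows = []
    for sample in samples:
        for rep in range(1, n_replicates + 1):
            rows.append(
                {
                    "sample_id": sample,
                    "gene_id": reference_gene,
                    "replicate": rep,
                    "ct": ref_ct + load[sample] + rng.normal(scale=noise_sd),
                }
            )
        for gene in effects.index:
            dct = (base_ct - ref_ct) + effects.loc[gene, sample]
            for rep in range(1, n_replicates + 1):
                rows.append(
                    {
                        "sample_id": sample,
                        "gene_id": gene,
                        "replicate": rep,
                        "ct": ref_ct + load[sample] + dct
                        + rng.normal(scale=noise_sd),
                    }
                )
    return pd.DataFrame(rows), effects.copy()


# ---------------------------------------------------------------------------
# Promoters with planted elements
# ---------------------------------------------------------------------------

def random_promoter(rng: np.random.Generator, length: int = 1500,
                    planted: list[tuple[int, str]] = ()) -> str:
    """Random nucleotide window with motifs planted at given offsets."""
    seq = list("".join(rng.choice(list("ACGT"), size=length)))
    for pos, motif in planted:
        seq[pos:pos + len(motif)] = list(motif)
    return "".join(seq)
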