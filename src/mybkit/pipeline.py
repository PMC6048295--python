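"""End-to-end orchestration: simulate -> scan -> phylo -> kaks -> structure
-> expression -> network -> promoter, from one declarative config.

Every stage reads and writes plain files (FASTA/GFF3/TSV/newick), so each is
independently re-runnable; the run manifest records parameters, input
digests and per-stage row counts, and a rerun with the same config and seed
is byte-identical.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .io_formats import (
    read_ct_table,
    read_fasta,
    read_gff3,
    read_matrix,
    sha256_of,
    write_ct_table,
    write_edge_list,
    write_fasta,
    write_gff3,
    write_matrix,
    write_newick,
)

log = logging.getLogger("mybkit")

STAGES = ("scan", "phylo", "kaks", "structure", "expression", "network", "promoter")


@dataclass
class PipelineConfig:
    """Paths, stage toggles and stage parameters for one pipeline run."""

    workdir: str = "."
    proteins: str = "proteins.fasta"
    cds_pairs: str = "cds_pairs.fasta"
    gene_models: str = "models.gff3"
    genome: str = "genome.fasta"
    expression: str = "expression.tsv"
    ct_table: str = "ct.tsv"
    outdir: str = "results"
    stages: tuple = STAGES
    seed: int = 0
    bootstrap_reps: int = 100
    min_support: float = 50.0
    distance_model: str = "poisson"
    pcc_cutoff: float = 0.85
    hub_k: int = 12
    fold_threshold: float = 2.0
    upstream_length: int = 1500
    reference_gene: str = "TIP41"
    calibrator_sample: str | None = None

    _REQUIRES = {
        "scan": ("proteins",),
        "phylo": ("proteins",),
        "kaks": ("cds_pairs",),
        "structure": ("gene_models", "proteins"),
        "expression": ("expression", "ct_table"),
        "network": ("expression",),
        "promoter": ("genome", "gene_models"),
    }

    def path(self, name: str) -> Path:
        return Path(self.workdir) / getattr(self, name)

    def validate(self):
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stages {sorted(unknown)}")
        for stage in self.stages:
            for inp in self._REQUIRES[stage]:
                p = self.path(inp)
                if not p.exists():
                    raise FileNotFoundError(
                        f"stage {stage!r} requires missing input {p}"
                    )
        if "structure" in self.stages and "scan" not in self.stages:
            raise ValueError("stage 'structure' needs the repeats of stage 'scan'")
        if "network" in self.stages and "expression" not in self.stages:
            raise ValueError("stage 'network' needs stage 'expression' outputs")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if "stages" in data:
            data["stages"] = tuple(data["stages"])
        return cls(**data)


def simulate_inputs(workdir, seed: int = 0, n_genes: int = 8,
                    n_pairs: int = 3) -> dict:
    """Write a complete synthetic input set (with truth files) to workdir."""
    from .family_scan import default_repeat_model
    from .synthetic_data import (
        ExprSimConfig,
        FamilySimConfig,
        myb_family_records,
        random_intron_spec,
        simulate_codon_pair,
        simulate_ct_table,
        simulate_expression,
        simulate_gene_model,
    )

    workdir = Path(workdir)
    workdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    model = default_repeat_model()

    fam = myb_family_records(n_genes, n_repeats=2, seed=seed, model=model)
    write_fasta([rec for rec, _ in fam], workdir / "proteins.fasta")
    pd.DataFrame(
        [
            {"gene_id": rec.id, "start": s, "end": e}
            for rec, spans in fam
            for s, e in spans
        ]
    ).to_csv(workdir / "repeats.truth.tsv", sep="\t", index=False)

    pair_records, pair_truth = [], []
    for k in range(n_pairs):
        cfg = FamilySimConfig(n_codons=200, target_ks=0.15, ka_ks_ratio=0.7,
                              seed=seed + 100 + k)
        a, b, truth = simulate_codon_pair(cfg)
        pair_records.append(a.__class__(f"pair{k + 1}_a", a.sequence))
        pair_records.append(b.__class__(f"pair{k + 1}_b", b.sequence))
        pair_truth.append({"pair": f"pair{k + 1}", **truth})
    write_fasta(pair_records, workdir / "cds_pairs.fasta")
    pd.DataFrame(pair_truth).to_csv(
        workdir / "cds_pairs.truth.tsv", sep="\t", index=False
    )

    models, phase_truth = [], []
    for k, (rec, _) in enumerate(fam):
        spec = random_intron_spec(rng, max_introns=3, n_codons=len(rec.sequence))
        strand = "+" if rng.random() < 0.5 else "-"
        m = simulate_gene_model(
            spec, n_codons=len(rec.sequence) + 1, gene_id=rec.id,
            seq_id="chr_sim", strand=strand, offset=1600 + 3000 * k,
        )
        models.append(m)
        for ci, ph in spec:
            phase_truth.append({"gene_id": rec.id, "codon_index": ci, "phase": ph})
    write_gff3(models, workdir / "models.gff3")
    pd.DataFrame(phase_truth).to_csv(
        workdir / "introns.truth.tsv", sep="\t", index=False
    )

    contig_len = 1600 + 3000 * n_genes + 2000
    genome = "".join(rng.choice(list("ACGT"), size=contig_len))
    write_fasta(
        [type(fam[0][0])("chr_sim", genome)], workdir / "genome.fasta"
    )

    expr_cfg = ExprSimConfig(seed=seed, responder_fraction=0.2, log2fc_effect=1.5)
    matrix, expr_truth = simulate_expression(expr_cfg)
    write_matrix(matrix, workdir / "expression.tsv")
    expr_truth.to_csv(workdir / "expression.truth.tsv", sep="\t", index=False)

    genes = [f"g{i + 1:03d}" for i in range(4)]
    samples = ["t0", "t1", "t3", "t6"]
    grid = pd.DataFrame(
        rng.normal(scale=1.5, size=(len(genes), len(samples))),
        index=genes, columns=samples,
    )
    grid["t0"] = 0.0
    ct, ct_truth = simulate_ct_table(grid, seed=seed)
    write_ct_table(ct, workdir / "ct.tsv")
    ct_truth.to_csv(workdir / "ct.truth.tsv", sep="\t", index_label="gene_id")

    return {"workdir": str(workdir), "n_genes": n_genes, "n_pairs": n_pairs}


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the configured stages in dependency order; return the manifest."""
    from . import expression_network as en
    from . import family_scan as fs
    from . import gene_structure as gs
    from . import molevol as me
    from . import phylo as ph
    from . import promoter_scan as ps

    config.validate()
    outdir = Path(config.workdir) / config.outdir
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "version": __version__,
        "seed": config.seed,
        "parameters": {
            k: v for k, v in vars(config).items() if not k.startswith("_")
        },
        "inputs": {},
        "stages": {},
    }
    for name in ("proteins", "cds_pairs", "gene_models", "genome",
                 "expression", "ct_table"):
        p = config.path(name)
        if p.exists():
            manifest["inputs"][name] = sha256_of(p)

    def record(stage, **counts):
        manifest["stages"][stage] = {"status": "complete", **counts}
        log.info("stage %s complete: %s", stage, counts)

    repeats_by_gene = {}
    if "scan" in config.stages:
        proteins = read_fasta(config.path("proteins"), alphabet="aa")
        model = fs.default_repeat_model()
        table = fs.family_table(proteins, model)
        table.to_csv(outdir / "families.tsv", sep="\t", index=False)
        rep_rows = []
        for rec in proteins:
            reps = fs.scan_repeats(rec, model)
            repeats_by_gene[rec.id] = reps
            for r in reps:
                rep_rows.append(
                    {
                        "gene_id": rec.id, "label": r.repeat_label,
                        "start": r.start, "end": r.end,
                        "score": round(r.score, 3),
                        "landmarks": r.landmark_residues,
                    }
                )
        pd.DataFrame(rep_rows).to_csv(outdir / "repeats.tsv", sep="\t", index=False)
        record("scan", n_proteins=len(proteins), n_repeats=len(rep_rows))

    if "phylo" in config.stages:
        proteins = read_fasta(config.path("proteins"), alphabet="aa")
        aln = ph.progressive_msa(proteins)
        tree = ph.bootstrap_support(
            aln, n_reps=config.bootstrap_reps, seed=config.seed,
            model=config.distance_model,
        )
        write_newick(tree, outdir / "tree.nwk")
        clades = ph.clades_at_support(tree, config.min_support)
        pd.DataFrame(
            [
                {"support": c.support, "size": len(c.clade),
                 "members": ",".join(sorted(c.clade))}
                for c in clades
            ]
        ).to_csv(outdir / "clades.tsv", sep="\t", index=False)
        record("phylo", n_taxa=len(proteins), n_clades=len(clades))

    if "kaks" in config.stages:
        cds = {r.id: r.sequence for r in read_fasta(config.path("cds_pairs"),
                                                    alphabet="nt")}
        pair_names = sorted({n.rsplit("_", 1)[0] for n in cds})
        triples = []
        for pname in pair_names:
            ca_nt, cb_nt = cds[f"{pname}_a"], cds[f"{pname}_b"]
            prot_a, prot_b = me.translate_cds(ca_nt), me.translate_cds(cb_nt)
            paln, _ = ph.global_align(prot_a, prot_b)
            ca = me.codon_align(paln, ca_nt, cb_nt)
            triples.append((f"{pname}_a", f"{pname}_b", ca))
        table = me.kaks_table(triples)
        table.to_csv(outdir / "kaks.tsv", sep="\t", index=False)
        record("kaks", n_pairs=len(table))

    if "structure" in config.stages:
        models = read_gff3(config.path("gene_models"))
        proteins = {r.id: r.sequence
                    for r in read_fasta(config.path("proteins"), alphabet="aa")}
        intron_rows, patterns = [], []
        for m in models:
            recs, n_utr = gs.intron_phases(m, proteins.get(m.gene_id))
            for r in recs:
                intron_rows.append(vars(r) | {"n_utr_introns": n_utr})
            patterns.append(
                gs.classify_pattern(m.gene_id, recs, repeats_by_gene.get(m.gene_id, []))
            )
        patterns = gs.assign_pattern_labels(patterns)
        pd.DataFrame(intron_rows).to_csv(outdir / "introns.tsv", sep="\t", index=False)
        per_gene, dist = gs.structure_summary(models, patterns)
        per_gene.to_csv(outdir / "structure.tsv", sep="\t", index=False)
        dist.to_csv(outdir / "patterns.tsv", sep="\t", index=False)
        record("structure", n_models=len(models), n_introns=len(intron_rows))

    matrix = None
    if "expression" in config.stages:
        matrix = read_matrix(config.path("expression"))
        flags = en.expression_groups(matrix)
        flags.to_csv(outdir / "expression_flags.tsv", sep="\t", index_label="gene_id")
        ct = read_ct_table(config.path("ct_table"), config.reference_gene)
        calibrator = config.calibrator_sample or sorted(ct["sample_id"].unique())[0]
        qpcr = en.ddct(ct, config.reference_gene, calibrator)
        qpcr.to_csv(outdir / "qpcr_fold_changes.tsv", sep="\t", index=False)
        folds = qpcr.pivot(index="gene_id", columns="sample_id",
                           values="fold_change")
        sets = en.responder_sets({"treatment": folds}, config.fold_threshold)
        pd.DataFrame(
            [
                {"treatment": s.treatment, "direction": d,
                 "genes": ",".join(sorted(g))}
                for s in sets
                for d, g in (("up", s.up), ("down", s.down))
            ]
        ).to_csv(outdir / "responders.tsv", sep="\t", index=False)
        record("expression", n_genes=matrix.values.shape[0],
               n_qpcr_rows=len(qpcr))

    if "network" in config.stages:
        net = en.build_network(matrix, cutoff=config.pcc_cutoff,
                               hub_k=config.hub_k)
        write_edge_list(net.edges, outdir / "edges.tsv")
        pd.Series(sorted(net.hubs), name="gene_id").to_csv(
            outdir / "hubs.tsv", sep="\t", index=False
        )
        record("network", n_edges=net.graph.number_of_edges(),
               n_hubs=len(net.hubs))

    if "promoter" in config.stages:
        genome = {r.id: r for r in read_fasta(config.path("genome"),
                                              alphabet="nt")}
        models = read_gff3(config.path("gene_models"))
        elements = ps.load_default_elements()
        all_hits = []
        for m in models:
            window = ps.extract_upstream(genome[m.seq_id], m,
                                         config.upstream_length)
            hits = ps.scan_elements(window, elements)
            all_hits.extend(
                {"gene_id": m.gene_id, "element": h.element,
                 "strand": h.strand, "start": h.start, "end": h.end}
                for h in hits
            )
        hits_df = pd.DataFrame(all_hits)
        hits_df.to_csv(outdir / "promoter_hits.tsv", sep="\t", index=False)
        record("promoter", n_hits=len(hits_df))

    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
    return manifest
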