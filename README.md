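# mybkit

A gene-family characterization toolkit for plant **R2R3MYB transcription
factors**, built for researchers studying the evolution and stress biology of
this family in grasses (the motivating system is moso bamboo, whose R2R3MYBs
include stress-responsive hub genes such as the *MYB4* group).

The MYB DNA-binding domain is a tandem array of ~52-residue helix-turn-helix
repeats, each with three regularly spaced tryptophans forming a hydrophobic
core; plant MYBs are classified by repeat count (1R "MYB-related", R2R3,
R1R2R3, 4R). `mybkit` implements the full characterization workflow as a
tested, reusable library + CLI, exercisable entirely on synthetic data with
known ground truth:

* **family_scan** — position-weight-model detection of MYB repeats
  (landmark tryptophans annotated, never enforced), family classification by
  repeat count, and ProtParam-style profiles (GRAVY, pI by net-charge
  bisection, molecular weight).
* **phylo** — affine-gap global alignment (Gotoh), minimal progressive MSA,
  p/Poisson distances with pairwise deletion, Saitou–Nei neighbor joining
  with explicit tie-breaks, column-bootstrap supports, and clade extraction
  at a support threshold.
* **molevol** — Nei–Gojobori (NG86) Ka/Ks: per-codon synonymous site
  fractions `S = Σ sᵢ`, pathway-averaged difference counts `Sd, Nd`
  (pathways through stops excluded), Jukes–Cantor correction
  `d = −¾ ln(1 − 4p/3)`, molecular-clock dating
  `T = Ks / (2λ)` with λ = 6.5 × 10⁻⁹ subs/site/year, and selection-regime
  calls (Ka/Ks < 1 purifying, ≈ 1 neutral, > 1 positive). Reciprocal-best-hit
  ortholog/paralog pairing and codon back-translation included.
* **gene_structure** — intron phases (phase ≡ coding offset mod 3) and
  splice-site pattern classes keyed to the R2/R3 repeat coordinates.
* **expression_network** — RPKM, 2^−ΔΔCT qPCR quantification,
  high/low-expression flags (RPKM > 10 in ≥ 1 stage; RPKM < 1 in > 2
  stages), fold-change responder sets (threshold 2) with Venn intersections,
  and the Pearson-correlation co-expression network (cutoff 0.85, positive
  edges, hubs = degree > 12).
* **promoter_scan** — IUPAC cis-element scanning of 1500-bp upstream
  windows on both strands.
* **synthetic_data** — generators for every input above, each returning the
  exact ground truth needed to score the downstream stage.

## Worked example

Simulate a diverged paralog pair and estimate its divergence:

```python
from mybkit.synthetic_data import FamilySimConfig, simulate_codon_pair
from mybkit.molevol import CodonAlignment, nei_gojobori, classify_selection

cfg = FamilySimConfig(n_codons=300, target_ks=0.12, ka_ks_ratio=0.7, seed=42)
a, b, truth = simulate_codon_pair(cfg)
r = nei_gojobori(CodonAlignment(a.sequence, b.sequence))
print(f"S = {r.S:.1f}  N = {r.N:.1f}  Sd = {r.Sd:.2f}  Nd = {r.Nd:.2f}")
print(f"Ks = {r.ks:.4f}  Ka = {r.ka:.4f}  Ka/Ks = {r.ratio:.4f}")
print(f"T = {r.t_mya:.2f} MYA  regime = {classify_selection(r.ratio).regime}")
```

prints

```
S = 231.8  N = 668.2  Sd = 21.00  Nd = 45.00
Ks = 0.0965  Ka = 0.0706  Ka/Ks = 0.7310
T = 7.43 MYA  regime = purifying
```

The 900 coding sites of the 300-codon pair split into ~232 synonymous and
~668 nonsynonymous sites; 21 synonymous and 45 nonsynonymous differences
give Ks ≈ 0.10 and Ka/Ks ≈ 0.73 (purifying selection), dating the
duplication to ~7 million years ago under the grass synonymous clock — the
age range of the whole-genome duplication that produced this family's recent
paralogs. The simulator's truth record confirms exactly 21 synonymous and 45
nonsynonymous events were applied.

The same analysis runs end-to-end from the shell:

```bash
mybkit simulate --workdir demo --seed 1   # synthetic inputs + truth files
mybkit kaks     --workdir demo            # results/kaks.tsv
mybkit network  --workdir demo            # results/edges.tsv, hubs.tsv
mybkit run --config pipeline.yaml         # all seven stages + manifest
```

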