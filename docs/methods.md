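# Methods

This note documents the models and procedures `mybkit` implements, the
defaults it ships, the design choices that were genuinely open, and what the
synthetic-data tests do and do not demonstrate.

## Coordinates and formats

All internal coordinates are 0-based half-open; conversion to the external
conventions (GFF3 1-based inclusive) happens only in `io_formats`. This
keeps the intron-phase arithmetic free of off-by-one adjustments. Sequences
are uppercased on read and `U` is mapped to `T` in nucleotide records; other
ambiguity codes are preserved. Gene models store exon/CDS intervals in
transcription order (descending genomic coordinates on the minus strand), so
downstream code never branches on strand.

## Repeat detection and family classification

The MYB repeat model is a 52-column position-weight matrix: pseudocounted
(α = 0.5) column frequencies from an alignment of repeat sequences, scored
as log2 odds against a uniform background. The packaged default model is
built from a small **synthetic** alignment
(`data/r2r3_repeat_alignment.synthetic.fasta`) constructed around the
canonical plant R2/R3 consensus with landmark tryptophans at columns 5, 25
and 45; any user alignment can replace it. The default score threshold is
set 6 standard deviations above the null window-score mean (null = i.i.d.
uniform residues), computed analytically from the weight matrix. At that
threshold chance hits in random sequence are vanishingly rare (the suite
verifies ≪ 1% of 1000 random 200-aa sequences produce any hit) while
sampled repeats score far above it.

Overlapping windows above threshold are resolved greedily by descending
score (ties: leftmost) — the single-best-hit behaviour of domain scanners —
and survivors are labelled N→C: R2/R3 for two repeats, R1/R2/R3 for three,
extras `R-extra`. Landmark columns only annotate a hit (the observed
residues are recorded); a substituted tryptophan, as found in the family's
ancient clade (W→M/R in R2, W→A in R3), never vetoes detection. Family
assignment is a pure function of repeat count: 0 → none, 1 → MYB-related,
2 → R2R3, 3 → R1R2R3, ≥ 4 → 4R. How partial or degenerate repeats should
count toward the "two or more repeats" rule is not standardized; here the
threshold decides, and it is configurable.

Physicochemical profiles: GRAVY is the mean Kyte–Doolittle hydropathy and
molecular weight the sum of average residue masses plus one water (both via
Biopython's ProtParam); pI is found by bisecting the net-charge curve to
1 × 10⁻⁴ pH with the EMBOSS pKa set. The pKa table is data, not code —
pI shifts by a few tenths between published tables — and can be swapped.

## Alignment and phylogeny

Pairwise alignment is Gotoh affine-gap global alignment (default BLOSUM62,
gap open 10, extend 0.5; a gap of length L costs open + L·extend). The
traceback tie-break (match > gap-in-b > gap-in-a) makes output
deterministic; the suite checks optimality against exhaustive enumeration at
short lengths and against an independent aligner's scores at longer ones.
The progressive MSA is deliberately minimal: a guide join order from
neighbor joining on fractional common k-mer (k = 3) distances, then
profile–profile Gotoh merges using mean inter-column substitution scores
(gaps contribute zero). It is adequate for the conserved-domain families it
serves here, not a ClustalX/MAFFT replacement.

Distances support p-distance and Poisson correction d = −ln(1 − p), with
pairwise deletion of gapped columns. The defaults (Poisson, pairwise
deletion) are the common protein-NJ defaults; the source analyses this
mirrors did not state their distance settings, so both are configurable.

Neighbor joining follows the Saitou–Nei Q criterion with two rules stated so
outputs are bit-reproducible: ties on Q break by the smallest (i, j) index
pair, and negative branch-length estimates are clamped to zero with a
warning. NJ is exact on additive matrices; the suite verifies topology
recovery for n ≤ 6 against exhaustive least-squares topology search and
against an independent library implementation.

Bootstrap supports resample alignment columns with replacement, rebuild the
NJ tree per replicate, and map bipartition frequencies onto the full-data
tree as integer-percent internal-node labels (round(100·f)). A fully
degenerate alignment (identical rows) carries no signal and is returned
without supports. Clade extraction reports every labelled internal edge
meeting the support and minimum-size thresholds — nested qualifying clades
are all reported — ordered by the lexicographic minimum of the leaf set.

## Ka/Ks and dating

`nei_gojobori` implements unweighted NG86. Per codon, each position
contributes (synonymous one-step changes)/3 to S, with mutations that create
stop codons counted as nonsynonymous in site counting; S is averaged over
the two sequences and N = 3·(codons) − S. Codon pairs differing at k
positions are averaged over all k! mutational pathways with equal weight;
pathways through stop codons are excluded (if every pathway is blocked — a
rare three-fold difference — all pathways are used with stop steps counted
nonsynonymous). Proportions ps = Sd/S and pn = Nd/N are corrected with
Jukes–Cantor; ps or pn ≥ 0.75 raises a saturation error. These conventions
are the most common published variant of NG86, and are stated explicitly
because the tools whose outputs this method mirrors do not document theirs.
No transition/transversion weighting is applied.

Identical sequences give ks = ka = 0 with the ratio reported as NaN (never
infinity); classification of NaN is "undetermined". The neutral call uses an
ε band (default 0.05) around Ka/Ks = 1 because exact float equality is
meaningless.

Divergence dates use T = Ks / (2λ) with λ = 6.5 × 10⁻⁹ synonymous
substitutions/site/year — the grass-lineage synonymous clock — reported in
MYA. The packaged table `data/phe_myb_divergence_pairs.tsv` carries
published Ka/Ks estimates for moso bamboo MYB ortholog/paralog pairs; its
ratio and MYA columns are closed-form functions of the printed Ka and Ks and
serve as a reference set. One published row (PheMYB3R) prints 102.00 MYA
where the formula gives 101.63 — a rounding anomaly in the source,
documented and excluded from agreement checks — and the published MYA column
mixes 1-dp and 2-dp rounding, so agreement is asserted to half a unit at
1 dp. Exact reproduction of published Ka and Ks from sequence data is not
claimed: the underlying genomes are outside this package's scope, and the
producing software's settings are unrecorded.

Reciprocal best hits use the global-alignment score; a pair is reported only
when each member is the other's unique best hit, and tied bests drop the
pair with a warning rather than guessing.

## Intron phases and splice patterns

With cds_offset the number of coding nucleotides 5′ of a splice site, phase
= cds_offset mod 3 (0: between codons; 1: after the first nucleotide; 2:
after the second) and the affected residue is cds_offset // 3. Introns lying
wholly in untranslated exons are counted separately, since published
exon/intron norms do not always state whether UTR introns are included.
Pattern keys record, per intron in transcription order, the region (R2, R3
or outside, with boundary sites assigned to the repeat via the closed-start
convention of half-open spans), the residue offset within the region, and
the phase. Keys get letters ('a' onward) in lexicographic key order over the
dataset — deterministic, but not claimed to match any published letter
assignment; the keys are the scientific content.

## Expression, qPCR and the network

RPKM = count / (length·kb⁻¹ · depth·10⁻⁶). Flags: highly expressed = RPKM
> 10 in at least one stage; lowly expressed = RPKM < 1 in more than two
stages. The four-group profile clustering is average linkage on 1 − PCC of
row-standardized profiles cut at four clusters; the grouping algorithm was
an open choice (the mirrored analyses never name one).

2^−ΔΔCT: replicate Cts are averaged; ΔCT = CT_target − CT_reference per
sample; ΔΔCT subtracts the calibrator sample's ΔCT; the calibrator's fold
change is exactly 1 by construction. Responder sets call a gene up when its
maximum fold across timepoints ≥ 2 and down when its minimum ≤ 0.5 (the
reciprocal bound; sources rarely state a numeric down threshold). The rare
gene qualifying in both directions is assigned to the larger |log2|
excursion so the sets partition. No significance test is attached — the
fold bound is the criterion, as in the mirrored analysis.

The co-expression network computes Pearson correlation on log2(x+1) values
(the scale underlying published PCC cutoffs is usually unstated; raw scale
is available via a flag), drops zero-variance genes with a warning, and adds
an edge when PCC ≥ 0.85. Only positive correlations form edges by default,
matching the published display of this family's network; `absolute=True`
opts into |PCC|. Hubs are nodes with strictly more than 12 edges.

## Synthetic data: what it emulates, and what it does not

* **Codon pairs** — sequence b derives from a by Poisson(Ks·S) synonymous
  and Poisson(Ka·N) nonsynonymous single-nucleotide events; each event picks
  a codon uniformly among those admitting its fate, then a change uniformly,
  never creating stops. Fate labelling makes the realized truth counts
  exact, and the calibration was verified to put the mean NG86 estimate
  within the Monte-Carlo error of the target at the defaults (500 codons,
  Ks 0.15, Ka/Ks 0.7). Not emulated: indels, transition bias (the config
  field is reserved), codon-usage bias, rate heterogeneity.
* **Planted proteins** — repeats are drawn column-wise from the model's
  frequencies with landmark tryptophans fixed, embedded in uniform-random
  spacers. Real negatives are not uniform-random sequence, so the measured
  false-positive rate bounds chance hits, not hits on real MYB-like decoys.
* **Gene models** — introns of fixed length inserted at requested
  (codon, phase) positions, CDS = exons (no UTR), both strands; recovery is
  exact by construction, which tests the coordinate bookkeeping, not splice
  biology.
* **Expression** — module genes share a latent N(0,1) log2 profile with
  population correlation exactly `within_module_rho` (measurement noise
  `noise_sd` is carved out of the idiosyncratic variance); responders gain a
  fixed log2 shift in the treated half of samples. Real expression has
  heavier tails, mean–variance coupling and correlated noise; passing edge
  recovery here demonstrates thresholding behaviour at known correlation,
  not performance on real RNA-seq.
* **Ct tables** — true ΔΔCT grid plus per-sample loading shifts and
  optional replicate noise; zero-noise recovery is exact.

Defaults for the expression generator (60 genes, 12 samples, 3 modules of
10, ρ = 0.95, noise 0.1) mirror the scale of the qPCR/RNA-seq panels in
this family's published co-expression analyses — a few dozen genes over
roughly a dozen conditions.

## Problem sizes in the automated checks

The acceptance script and suite run at sizes chosen to make the checks
sharp but cheap: 200 replicate codon pairs of 500 codons for estimator
recovery; 1000 random 10-codon alignments plus every sense-codon pair for
oracle equivalence; 30 random additive matrices (n = 4–6) with exhaustive
topology search; two 3-taxon clades at 120 columns with 100 bootstrap
replicates; 100 random gene models; 5 replicate expression datasets pooled
for edge-recovery F1. Edge-recovery F1 is pooled across replicates because a
single 12-sample dataset yields a high-variance F1 estimate of the same
underlying recovery rate.

## Known limitations

* The progressive MSA has no iterative refinement; deeply diverged or
  repeat-shuffled families may misalign outside the conserved domain.
* NG86 is a counting method: no ML (Goldman–Yang) Ka/Ks, no sliding
  windows, no codon-frequency corrections.
* The repeat scanner has no indel states; repeats with internal insertions
  or deletions relative to the 52-column model will score poorly.
* Published dataset-level counts for the motivating genome (e.g. family
  sizes, clade counts, modal pattern percentages) depend on external genome
  data and are not reproduced here; the suite demonstrates the machinery on
  synthetic data with known truth.
* Alphabet detection for alignment inputs is heuristic (nucleotide only on
  positive T/U evidence); pass explicit types for unusual inputs.
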