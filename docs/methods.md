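# Methods

This note documents the models, numerical choices, and validation design
behind genefamkit, in the order the pipeline runs them.

## Identification funnel

Candidates are the non-redundant subject identifiers of similarity hits
with E-value strictly below the threshold (default 1e-10); "non-redundant"
is interpreted as unique subject ids, and reference proteins appearing as
subjects are excluded. The domain filter is conjunctive: a candidate must
have at least one hit for *every* required Pfam accession (default PF00122,
the E1–E2 ATPase domain, and PF00702, the haloacid dehalogenase-like
hydrolase domain). No domain E-value cutoff is applied by default — the
similarity threshold already controls specificity — but an optional
independent-E-value cutoff flag exists.

Diagnostic motifs (TGE, DKTGT, CPC/SPC as `[CS]PC`, GDGxNDxP as
`GDG.ND.P`, HP, PxxK as `P..K`) are reported with positions but never used
to filter: the HP dipeptide in particular has a chance occurrence rate of
roughly L/400 in a random protein of length L, and the motif panel is
descriptive in the underlying workflow.

Clade confirmation midpoint-roots the candidate tree and keeps the
candidates inside the smallest clade containing all reference proteins.
Midpoint rooting makes the clade reproducible on an otherwise unrooted NJ
tree. Two tree routes exist: for candidate sets that may contain unrelated
negatives, distances come from per-pair global alignments
(`pairwise_poisson_distance`), because a single multiple alignment
misaligns unrelated sequences and can destabilize the root; the
family+reference tree used for grouping and bootstrap is built from the
multiple alignment as usual.

## Physicochemical panel

All indices use bundled published constant tables (`physchem_data.py`):
ExPASy average residue masses plus one water (18.01524 Da); Kyte–Doolittle
hydropathy; the Guruprasad, Reddy & Pandit 400-entry dipeptide instability
weights, index = (10/L) Σ DIWV(i, i+1), stable below 40; Ikai aliphatic
index in mole percent. pI solves net charge = 0 by bisection on [0, 14] to
1e-6 pH units with the Bjellqvist pK set as used by the ProtParam service,
with one deliberate simplification: the termini use the generic pK values
(N-terminus 7.5, C-terminus 3.55) without residue-specific adjustment.
Published pI values computed with residue-specific terminal pKs can
therefore differ by up to ~0.3 units; all side-chain chemistry is
identical. Unknown residues (X) are excluded from sums and tolerated up to
5% of the chain (configurable); beyond that the profile is refused.

## Phylogeny

Distances are Poisson-corrected amino-acid distances d = −ln(1 − p). The
deletion rule defaults to complete deletion (only columns without gaps in
any row are compared; the same column set for every pair); pairwise
deletion is available. p ≥ 1 − 1e-6 is clamped and the pair flagged
saturated.

Neighbor joining is the standard Saitou–Nei agglomeration on the Q
criterion. Ties in Q are broken by the lexicographically smallest pair of
subtree keys (a subtree's key is its smallest leaf id), so topologies are
platform-independent. Negative branch lengths at a join are clamped to
zero with the deficit moved to the sibling branch, preserving their sum.
On additive matrices the algorithm recovers the generating topology and
branch lengths exactly (tested against construct-then-recover oracles up
to 8 leaves).

Bootstrap resamples alignment columns with replacement, rebuilds the NJ
tree, and reports for each internal bipartition of the point-estimate tree
the percentage of replicates containing it. The point estimate never
depends on the seed.

Group assignment midpoint-roots the tree and gives each non-reference leaf
the majority reference group of the smallest clade containing it and at
least one reference; a leaf whose smallest such clade is the whole tree is
"ungrouped", and an exact majority tie is "ambiguous" rather than a silent
choice.

The bundled center-star aligner (global Needleman–Wunsch, BLOSUM62, gap
open −10 / extend −0.5, center = maximal summed pairwise score) exists so
synthetic runs are self-contained; any external aligner's FASTA output can
be used instead.

## Ka/Ks and dating

Nei–Gojobori (1986) counting: each codon position contributes the fraction
of its three possible changes that are synonymous; changes producing stop
codons count as nonsynonymous, which makes S + N = 3 × codons exact. For a
codon pair differing at k positions, Sd/Nd are averaged over all k!
substitution orders; orders passing through a stop codon are excluded
unless all do (NG86 implementations differ here; this is the documented
choice, validated against brute-force enumeration). Proportions pS = Sd/S
and pN = Nd/N get the Jukes–Cantor correction d = −(3/4) ln(1 − 4p/3),
with a saturation error at p ≥ 3/4. ω is reported as missing (not 0 or ∞)
when Ks = 0. Divergence time is T = Ks/(2λ) with λ = 8.12 × 10⁻⁹
synonymous substitutions per site per year (the peanut rate) by default.
Codon alignments are built by back-threading a protein alignment; columns
gapped on either side are dropped.

## Duplication classification

Collinear blocks are chains of homologous gene pairs monotone in gene rank
on both chromosomes (both orientations searched), found by dynamic
programming with per-step rank gap ≤ 25 and kept at ≥ 5 anchors —
MCScanX's customary MATCH_SIZE — with score = anchor count (no E-value
weighting; a documented simplification). Classification precedence is
total: tandem (same chromosome, rank gap ≤ 2) > whole-genome (anchor of a
block joining homeologous chromosomes, by default Chr.i ↔ Chr.i+10 for a
two-subgenome allotetraploid) > segmental (anchor of any other block) >
dispersed. An optional Ks window can additionally gate the whole-genome
label, reflecting that allopolyploidy puts its pairs in a narrow low-Ks
band; the homeolog-map rule is a reconstruction validated on synthetic
truth, since tools reporting WGD/segmental labels rarely state their rule.

## Gene structure comparison

Exon junctions are expressed in spliced-CDS coordinates and mapped between
the two members through the protein alignment (never a genomic alignment,
so intron sequences are not needed). Rules: different intron counts →
gain/loss; equal counts with a junction displaced by more than 3 nt →
exonization/pseudoexonization; equal counts, junctions conserved, but an
exon length changed by ≥ 9 nt → insertion/deletion; otherwise identical.
The 3 nt junction tolerance and 9 nt indel threshold are declared defaults
validated only against synthetic truth. A comparison reports a *set* of
mechanisms; "identical" is exclusive.

## Expression and qPCR statistics

TPM matrices are transformed to lg = log10(TPM+1) and per-gene Z scores
(population SD; constant rows → zero with a flag). Gene clustering is
average-linkage agglomerative clustering on the Z layer (Euclidean by
default, correlation distance available), cut to k clusters (default 2) and
numbered by descending mean lg expression so cluster 1 is the
high-expression cluster.

ΔΔCT: ΔCt = Ct(target) − Ct(reference) per replicate; the calibrator is
the mean control ΔCt of the same gene × cultivar (the usual convention
when the calibrator sample is unstated); fold = 2^(−ΔΔCt). Means ± SE are
computed on the fold scale over replicates, matching how such results are
plotted. By construction the geometric mean of control folds is exactly 1.

Duncan's multiple range test uses the studentized-range quantile at the
protection level α_p = 1 − (1 − α)^(p−1) for a span of p ordered means,
with MS_error from the one-way ANOVA and the harmonic mean group size;
quantiles come from the studentized-range distribution rather than
hard-coded tables (verified against the published 5% table). The compact
letter display assigns one letter per maximal contiguous run of mutually
non-significant means, which cannot produce transitivity violations. With
zero within-group variance everywhere, F is flagged undefined and letters
fall back to exact mean equality.

Pearson correlations use t = r√(n−2)/√(1−r²) with two-sided p from the t
distribution; marks are * (p < 0.05) and ** (p < 0.01), and constant
vectors yield a flagged undefined r.

## Synthetic data: what is emulated, and what is not

The generator plants a complete study: a 20-chromosome allotetraploid
genome (10 chromosomes per subgenome, 30 genes each, 600 genes total at
default scale); a 21-member family in six subfamilies with exactly 10
whole-genome pairs (homeologous placements at matching ranks inside
planted collinear runs of 8 anchors), 4 segmental pairs (within-subgenome
runs, high Ks), and 1 tandem pair (adjacent ranks); diagnostic motifs
embedded at fixed positions in every family protein and scrubbed from
background genes; planted negatives for the funnel (decoys with hits but a
missing domain, and a coherent sister clade with both domains that must be
excluded by the tree stage); a two-cluster tissue expression pattern; and
qPCR Ct values with planted cultivar × treatment log2 fold changes whose
Zn effects co-vary with planted Zn concentrations in the metal table, so
expression–accumulation correlations are recoverable at n = 24
(2 cultivars × 4 treatments × 3 replicates).

Divergence is a uniform-rate codon substitution process: synonymous event
counts are Poisson with mean Ks × S and nonsynonymous with mean
ω × Ks × N; proposals creating stops are rejected, and nonsynonymous
proposals inside motif spans are rejected (event counts, hence planted
rates, are unaffected — only placement is constrained). Realized event
counts are written to the truth table, so recovery tests compare the
estimator against what was actually applied. Family CDS are 300 codons at
bundle scale; the parameter-recovery harness uses 1000 codons, the scale
of the real transporter CDS (≈2.4–4.0 kb). Structural divergence is
planted as explicit edits on the derived member of a WGD pair: exon
splitting (gain/loss), a 30 nt mid-exon insertion (insertion/deletion), or
a 15 nt junction extension (exonization); junctions and edit positions
avoid motif interiors.

Deliberately not emulated: intron sequence evolution and genomic
alignment; codon-level indels (structural edits are codon-aligned
insertions); transition/transversion bias or among-site rate variation
(the NG86+JC estimator assumes neither, so recovery tests validate the
implementation, not robustness to model violation); read-level RNA-seq
(TPM matrices are drawn directly); and real-proteome scale. Passing the
recovery suite therefore demonstrates correctness of the algorithms under
their own model assumptions, not performance on real divergent genomes.

Determinism: one `numpy` Generator per artifact, each seeded as
(master seed, artifact index), so outputs are byte-identical at a fixed
seed and adding an artifact never perturbs the others.

## Problem sizes in the validation suite

The test suite and acceptance script run at desk scale by design: the
default bundle (600 genes, 21-member family), 100 bootstrap replicates for
support checks, 500 random codon pairs against the enumeration oracle, and
50 simulated pairs per cell of the {ω ∈ 0.1/0.2/0.5} × {Ks ∈
0.02/0.1/0.5} recovery grid. At these sizes the whole suite completes in
about a minute on one core.
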