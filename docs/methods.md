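# Methods

## Scope and model

The package analyzes fungal NLR repertoires in five stages: resolution of
competing HMM domain predictions into per-gene architectures, motif-based
typing of the nucleotide-binding (NB) domain, alignment-free comparison and
ordination of NB fragments, detection and null-calibration of NLR gene
clusters, and phylogenetically corrected regression of repertoire size on
genome features. A synthetic-data module generates all inputs with the
statistical structure these stages assume.

## Domain annotation resolution

Hits are read from HMMER3 per-domain tables (envelope coordinates,
independent E-values). Hits on one gene compete when their amino-acid
intervals overlap by at least a fraction (default 0.5) of the shorter
interval; competition is closed transitively, so a chain of overlaps forms
one competition group. Groups containing several profile sources are
decided by source priority alone: curated fungal-NLR profiles over
order-specific profiles over Pfam-A. Within a single source the best
(lowest-E-value) hit is retained only if its E-value is strictly smaller
than the squared E-value of *every* competitor — the plural reading of the
rule, rather than best-versus-second-best. When the test fails, an
NB-class competition is recorded as an NB of undetermined type (the domain
is present; its identity is not), and any other competition keeps all hits.
E-values of exactly zero are floored at 1e-300 before squaring.

Two choices the annotation sources leave open are fixed here: a call is
assigned to the N- or C-terminal side by its midpoint relative to the NB
region midpoint, and nested (fully contained) hits compete like any other
overlap. Candidate NLRs require an NB call, a canonical C-terminal repeat
call (Ankyrin, TPR, WD40, HEAT) starting downstream of the NB end, and gene
length strictly greater than 1000 bp. Architecture classes use truncation
thresholds of 20 aa (N-terminal) and 50 aa (C-terminal): a side with no
call and less flanking room than the threshold is "missing", with room is
"undetermined"; two or more distinct canonical categories on one side make
the gene "mixed" (which outranks the other labels, since it signals a
fused or mispredicted model rather than a clean tripartite gene).

The profile→category map merges sesA into HeLo-like and NAD1 into
Goodbye-like, pools amyloid-motif profiles under "amyloid" (counted among
canonical N-terminal categories), and passes unknown profiles through as
non-canonical categories named after the profile.

Interval merging for alignment-hit post-processing treats closed integer
intervals that share an endpoint *or abut* (end + 1 = next start) as one
covered run, returning the minimal disjoint cover of the union. Alignment
hits are retained when their score is ≥ 200 (configurable), they overlap an
NB interval by ≥ 1 bp, and they carry neither stop codons nor frameshifts.

## NB typing

The degenerate-motif engine accepts literals, bracketed residue classes,
`h` (hydrophobic, default set {A,C,F,I,L,M,V,W,Y}, configurable), and `x`
(any residue; the ambiguity code X matches only `x`). Walker B
classification: the NACHT consensus `hhhhD[GAS]hDE` anywhere in the
sequence wins outright; otherwise `hhhhD[DE]` (first aspartate directly
followed by an acidic residue) gives NB-ARC; otherwise neither. The
leftmost match of the winning motif is the reported Walker B. NACHT
subtyping searches the NAIP-like HETHS consensus `FhHxxhQE[YF]hxA` strictly
downstream of the Walker B end (the HETHS lies C-terminal of the core
P-loop domain); a hit gives N-NACHT, none gives T-NACHT. The NB-ARC Walker
B is stated in the literature only negatively (no small residue after the
first aspartate, a directly following acidic residue instead); `hhhhD[DE]`
is its minimal positive operationalization.

NB sequences are split into two fragments at the *start* of the Walker B
motif — fragment 1 is everything N-terminal of it, fragment 2 runs from the
Walker B start to the C-terminus — so the two fragments concatenate back to
the input. (An alternative convention splits between Walker A and Walker B;
the start-of-Walker-B rule is used consistently here.)

## Alignment-free distances and ordination

Three pairwise dissimilarities are implemented explicitly rather than
delegated, because their exact formulas are what downstream assertions rely
on:

* normalized Google distance on k-mer sets (default k = 3; word sizes are
  configurable since published analyses also used 2 and 4):
  `d = (|A|+|B|-2|A∩B|) / (|A|+|B|-|A∩B|)`, 0 for identical sets, 1 for
  disjoint ones;
* Lempel–Ziv complexity distance in the Otu–Sayood normalized form,
  `d = max{C(xy)-C(x), C(yx)-C(y)} / max{C(x),C(y)}`, with C(.) the LZ76
  exhaustive-history production count (Kaspar–Schuster algorithm; verified
  in tests against a direct implementation of the definition);
* BLOSUM62 dissimilarity of gap-aligned pairs over columns where neither
  sequence is gapped: `d = 1 - S₁₂/max(S₁₁,S₂₂)` with Sxy the summed
  substitution scores; this reproduces Biopython's protein
  DistanceCalculator exactly (checked in tests).

Ordination is classical (Torgerson) scaling: Gower-center `-D²/2`,
eigendecompose, scale eigenvectors by square roots of the positive
eigenvalues. Negative eigenvalues from non-Euclidean inputs are reported
and their axes dropped; the positivity tolerance is 1e-12 relative to the
leading eigenvalue.

## Cluster genomics

A cluster is a maximal run of NLRs on one contig whose consecutive pairs
satisfy both a base-pair gap bound and an intervening-gene bound. The
working thresholds are inclusive (gap ≤ 40 000 bp, intervening ≤ 8),
matching the calibration grid semantics; a strict (<) mode is available.
The gap is measured between facing gene boundaries (downstream start −
upstream end − 1) and floored at zero for overlapping gene models.

The permutation null relabels, per replicate, a uniform random gene subset
(drawn without replacement over all genes, NLRs included) of the observed
NLR count, and recounts clustered genes. Calibration scores every
(gap, intervening) grid point — default grids: the 27 gap values 0–200 kb
and intervening counts 0–8 — by the fraction of genomes at which the point
attains that genome's maximal excess of observed over null-mean clustered
counts; ties break toward the smaller gap, then the smaller intervening
count. One set of permutations per genome is shared across the grid, which
makes excesses comparable between grid points and keeps the cost linear in
the grid size.

Head-to-head pairs: a two-member cluster whose upstream gene is on the
minus strand and downstream gene on the plus strand (divergent 5′-to-5′
orientation). Larger clusters are reported as not applicable rather than
scanned for internal pairs.

## Comparative statistics

PGLS places on the regression residuals the covariance
`V(λ) = λ·C + (1-λ)·diag(C)`, where C holds shared root-to-tip branch
lengths. λ is estimated by maximizing the profile log-likelihood over
[0, 1] with a bounded scalar search (tolerance 1e-6) plus explicit
evaluation of both boundary values. The GLS solve whitens through the
Cholesky factor of V with a relative ridge of 1e-10 on the diagonal —
needed because simulated trees can carry near-zero sister branches that
make V numerically singular; the ridge sits far below estimation error.
Adjusted R² is computed in the whitened space against the GLS
intercept-only fit; the slope p-value is a two-sided t-test with n − 2
degrees of freedom. With λ = 0 the fit reduces to (depth-weighted) ordinary
least squares, which the tests exploit as a closed-form oracle.

The inflation selector returns the first inflation value of the earliest
run of three consecutive equal NLR counts, or none when no plateau exists.
Repertoire shares are rounded half away from zero: one decimal for NB-type
shares, integers for cross-tab rows, matching the conventions of published
repertoire tables. Combination-space accounting multiplies category counts
(e.g. 8 × 3 = 24, 3 × 4 = 12, 8 × 3 × 4 = 96) and counts distinct observed
tuples and their projections.

The Bayesian threshold model sometimes used for binary traits on
phylogenies is out of scope; so are the Kruskal–Wallis/Wilcoxon family
comparisons (any statistics library serves) and orthology inference itself
(only the inflation-selection rule over its output table is implemented).

## Synthetic data: what it emulates, and what it does not

Gene tables are scaled-down fungal assemblies: 10 contigs × 150 genes,
gene lengths 1.2–3 kb, intergenic gaps 0.2–3 kb, 20 NLRs (≈1.3% of genes —
real assemblies run ≈0.6%, about 10,600 genes with ≈60 NLRs; the scaled
genome keeps the density within a factor of ~2 so permutation nulls remain
informative). Planted clusters satisfy the (40 kb, 8) definition by
construction: intervening genes inside a cluster block take the minimum
gene length and a clamped gap so consecutive NLRs sit within the
`within_cluster_gap_bp` budget. Distinct NLR groups are separated by at
least nine non-NLR genes — one more than the largest intervening bound on
the calibration grid — so planted structure is exactly recoverable and no
spurious merges occur. Head-to-head pairs are planted as additional
adjacent −/+ NLR pairs (extra size-2 clusters); the first member of every
ordinary planted cluster sits on the plus strand so that no unplanned
divergent pair arises. The generator raises on infeasible requests (more
clustered NLRs than `n_nlr`, blocks that cannot fit, budgets too small for
the requested intervening genes).

Proteins are uniform-random backgrounds with motif instances planted at
fixed offsets (Walker A `GxxxxGK[ST]` — the classical P-loop, as the
specific consensus is not printed in the repertoire literature; the
type-appropriate Walker B; for NACHT types a HETHS block, NAIP-like for
N-NACHT and a TLP1-like stand-in `hhHxxhRDhhxG` — whose fixed R/D core
cannot satisfy the NAIP Q-E core — for T-NACHT). The background is redrawn
(rejection sampling, seeded, deterministic) until no unintended Walker B or
NAIP-HETHS match remains anywhere, so a typing error can only indict the
classifier, never background noise. `corrupt_motif` mutates exactly one
diagnostic position of a named planted motif to proline, which lies outside
every motif class used (not hydrophobic, not acidic, not G/A/S).

Fragment families for ordination derive each member from a per-type
template by substituting non-motif positions independently (default 20%),
emulating diverged homologous families that share type-specific motif
blocks. Trait data follow y = intercept + slope·x + e with x independent
standard normal per tip and e multivariate normal with covariance
sigma² × shared-branch-length matrix; trees come from a seeded pure-birth
process.

What passing tests do *not* show about real data: synthetic backgrounds are
i.i.d. uniform (real proteomes have composition bias and repeats that can
produce chance motif hits); domain-hit E-values are log-uniform on
[1e-30, 1e-4] and independent of region length; gene tables have no
nucleotide sequence, introns, or repeat-induced point mutation; and the
fragment families diverge by uniform substitution without indels. Accuracy
of 100% on planted structure is a correctness statement about the rules,
not an error-rate estimate for real genomes.

## Problem sizes and numerical conventions

The test suite and the acceptance script use: 1000 proteins per NB type for
typing recovery; 20 genomes for calling and cluster recovery; 200 random
tables of ≤50 genes against the exhaustive cluster oracle; fragment sets of
50 T-NACHT / 20 NB-ARC / 4 N-NACHT (the scaled-down counterpart of the
325/85/4 orthogroup sample) for ordination; 100 replicates on a 64-tip tree
for PGLS slope recovery; permutation nulls of 200 replicates in the
analysis drivers (the full procedure uses 1000). PCoA round-trips on
Euclidean inputs hold to 1e-9; PGLS at λ = 0 matches closed-form weighted
OLS to 1e-8. All generators and permutations are bit-reproducible under
their seeds.
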