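# nlrscape

Analysis toolkit for fungal NOD-like receptor (NLR) repertoires.

Fungal NLRs are intracellular immune receptors with a tripartite
architecture: an N-terminal effector domain (HeLo-like, sesB-like,
Goodbye-like, HET-like, PNP_UDP_1, RelA_SpoT, Patatin, or an amyloid
motif), a central nucleotide-binding (NB) domain of the NACHT or NB-ARC
lineage, and C-terminal superstructure-forming repeats (Ankyrin, TPR, WD40,
HEAT). Characterizing a genome's NLR repertoire means resolving noisy,
overlapping HMM domain predictions into per-gene architectures, typing the
NB domain from degenerate sequence motifs, and asking how NLR genes are
organized along chromosomes and across a phylogeny. This package implements
that pipeline for anyone studying repertoire evolution in filamentous
fungi, with a synthetic-data generator that plants every kind of structure
the pipeline detects, so the whole analysis is testable without genome
downloads.

## What it computes

* **Domain annotation resolution** (`domain_annotation`). Competing hits
  from three profile collections (curated fungal-NLR profiles > order-
  specific profiles > Pfam-A) are resolved by source priority; within one
  source the best hit is kept only when its E-value `e₁` beats the *square*
  of every competitor's: `e₁ < eⱼ²` for all j. A candidate NLR is a gene
  longer than 1 kb with an NB call and a canonical C-terminal repeat call
  downstream of it.
* **NB typing** (`nb_typing`). The Walker B consensus `hhhhD[GAS]hDE`
  (h = hydrophobic) diagnoses NACHT; `hhhhD[DE]` — the first aspartate
  directly followed by an acidic residue — diagnoses NB-ARC. A NACHT
  sequence carrying the NAIP-like HETHS consensus `FhHxxhQE[YF]hxA`
  downstream of its Walker B is the rare N-NACHT; otherwise it is the
  common T-NACHT.
* **Alignment-free ordination** (`alignment_free`). NB sequences split at
  the Walker B start; fragments compared by the normalized Google distance
  on k-mer sets, `d = (|A|+|B|-2|A∩B|)/(|A|+|B|-|A∩B|)`, and the
  Lempel–Ziv complexity distance
  `d = max{C(xy)-C(x), C(yx)-C(y)} / max{C(x),C(y)}`; matrices embedded by
  classical principal coordinates analysis. A BLOSUM62 score dissimilarity
  `d = 1 - S₁₂ / max(S₁₁,S₂₂)` serves aligned-pair comparisons.
* **Cluster genomics** (`cluster_genomics`). An NLR cluster is a maximal
  run of two or more NLRs with consecutive pairs separated by at most 40 kb
  and at most 8 non-NLR genes (configurable, strict mode available). The
  parameters are calibrated against a permutation null (random gene subsets
  of the observed NLR count), and two-gene clusters in divergent −/+
  orientation are flagged head-to-head.
* **Comparative statistics** (`comparative_stats`). Phylogenetic
  generalized least squares with maximum-likelihood Pagel's λ, the Markov-
  clustering inflation plateau selector, repertoire share tables, and
  domain-combination space accounting (8 × 3 = 24 N-terminal/NB,
  3 × 4 = 12 NB/C-terminal, 96 tripartite combinations).
* **Synthetic data** (`synthetic_data`). Gene tables with planted clusters
  and head-to-head pairs, proteins with planted Walker A / Walker B / HETHS
  motifs, domain-hit tables with log-uniform E-values and controlled
  decoys, and Brownian trait data on simulated trees.

## Worked example

```python
from nlrscape.nb_typing import type_nb_domain
from nlrscape.synthetic_data import SyntheticProteinSpec, generate_nb_protein

seq = generate_nb_protein(SyntheticProteinSpec(nb_type="N-NACHT", seed=5))
call = type_nb_domain(seq)
print(call.nb_type, call.walkerB_match.aa_start, call.heths_match.aa_start)
```

prints

```
N-NACHT 120 220
```

— the planted NAIP-like NACHT protein is recovered with its Walker B at
position 120 and its HETHS motif at position 220, exactly where the spec
placed them.

The numbered scripts under `analysis/` run the full narrative on a
simulated cohort (`python analysis/01_simulate_inputs.py` …); each prints
what it found and writes its tables under `results/`. On the default
cohort, NLR calling and NB typing recover the planted truth exactly
(20/20 genomes, 150/150 proteins), the first principal coordinate separates
NB-ARC from NACHT fragments with a silhouette of 0.86, all 20 genomes show
more clustered NLRs than the permutation null, and PGLS recovers the
generating slope of 2.0.

There is also a thin CLI (`nlrscape simulate|annotate|type-nb|afdist|pcoa|
cluster|pgls|summarize|plateau`) over the same functions.

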