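"""NLR cluster detection, permutation-null calibration, and head-to-head pairs.

A cluster is a maximal run of two or more NLR genes on one contig in which
every consecutive NLR pair is separated by at most ``max_gap_bp`` of
intervening sequence and at most ``max_intervening`` non-NLR genes (defaults
40 kb and 8; a strict mode uses ``<`` instead of ``<=``).  The parameters are
calibrated against a permutation null: relabel a uniform random gene subset,
of the same size as the observed NLR set, as NLR and recount; a (gap,
intervening) grid point scores by the fraction of genomes at which it attains
the genome's maximal excess of observed over null-mean clustered counts.

A two-member cluster is head-to-head when the upstream gene lies on the minus
strand and the downstream gene on the plus strand (divergent 5'-to-5'
orientation, the sensor/helper arrangement of paired plant NLRs).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

GENE_COLUMNS = ["gene_id", "contig", "start", "end", "strand", "is_nlr"]

#: The calibration grid of maximum inter-NLR distances (bp).
DEFAULT_GAP_GRID_BP = tuple(
    int(kb * 1000)
    for kb in (0, 0.5, 1, 1.5, 2, 2.5, 3, 3.5, 4, 4.5, 5, 6, 7, 8, 9, 10,
               15, 20, 25, 30, 35, 40, 45, 50, 100, 150, 200)
)
#: The calibration grid of maximum intervening non-NLR gene counts.
DEFAULT_INTERVENING_GRID = tuple(range(9))


@dataclass(frozen=True)
class ClusterParams:
    max_gap_bp: int = 40_000
    max_intervening: int = 8
    strict: bool = False  # True: use < instead of <=

    def __post_init__(self):
        if self.max_gap_bp < 0 or self.max_intervening < 0:
            raise ValueError("cluster parameters must be non-negative")


@dataclass(frozen=True)
class NLRCluster:
    contig: str
    members: tuple  # gene ids, coordinate order
    head_to_head: bool = False

    def __len__(self):
        return len(self.members)


@dataclass
class PermutationNullSummary:
    observed: int
    mean: float
    sd: float
    counts: np.ndarray = field(repr=False)


def _validate_genes(genes: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in GENE_COLUMNS if c not in genes.columns]
    if missing:
        raise ValueError(f"gene table missing columns: {missing}")
    if genes["gene_id"].duplicated().any():
        raise ValueError("duplicate gene identifiers")
    if (genes["start"] > genes["end"]).any():
        raise ValueError("gene start after end")
    return genes.sort_values(["contig", "start"], kind="mergesort").reset_index(drop=True)


def _linked_runs(starts, ends, nlr_idx, params: ClusterParams):
    """Runs of consecutive NLRs (by index into the sorted contig gene list)
    whose pairwise links satisfy the cluster parameters."""
    if len(nlr_idx) < 2:
        return []
    gaps = starts[nlr_idx[1:]] - ends[nlr_idx[:-1]] - 1
    gaps = np.maximum(gaps, 0)  # overlapping genes: gap treated as 0
    intervening = nlr_idx[1:] - nlr_idx[:-1] - 1
    if params.strict:
        linked = (gaps < params.max_gap_bp) & (intervening < params.max_intervening)
    else:
        linked = (gaps <= params.max_gap_bp) & (intervening <= params.max_intervening)
    runs = []
    run_start = None
    for i, ok in enumerate(linked):
        if ok and run_start is None:
            run_start = i
        elif not ok and run_start is not None:
            runs.append((run_start, i))  # member indices nlr_idx[run_start..i]
            run_start = None
    if run_start is not None:
        runs.append((run_start, len(linked)))
    return runs


def detect_clusters(genes: pd.DataFrame, params: ClusterParams = ClusterParams()) -> list[NLRCluster]:
    """Maximal NLR runs satisfying the (gap, intervening) parameters."""
    genes = _validate_genes(genes)
    clusters = []
    for contig, sub in genes.groupby("contig", sort=True):
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        nlr_idx = np.flatnonzero(sub["is_nlr"].to_numpy())
        gene_ids = sub["gene_id"].to_numpy()
        strands = sub["strand"].to_numpy()
        for a, b in _linked_runs(starts, ends, nlr_idx, params):
            member_idx = nlr_idx[a : b + 1]
            members = tuple(gene_ids[member_idx])
            h2h = (
                len(members) == 2
                and strands[member_idx[0]] == "-"
                and strands[member_idx[1]] == "+"
            )
            clusters.append(NLRCluster(str(contig), members, h2h))
    return clusters


def detect_head_to_head(cluster: NLRCluster, genes: pd.DataFrame) -> bool:
    """True for a two-member cluster whose genes diverge (strands -,+ in
    coordinate order); clusters of any other size are not applicable."""
    if len(cluster) != 2:
        return False
    genes = _validate_genes(genes)
    sub = genes[genes["gene_id"].isin(cluster.members)].sort_values("start")
    strands = sub["strand"].tolist()
    return strands == ["-", "+"]


def count_clustered(genes: pd.DataFrame, params: ClusterParams = ClusterParams()) -> int:
    """Total number of NLR genes that belong to some cluster."""
    return sum(len(c) for c in detect_clusters(genes, params))


def _count_clustered_mask(starts_by_contig, ends_by_contig, mask_by_contig, params) -> int:
    total = 0
    for starts, ends, mask in zip(starts_by_contig, ends_by_contig, mask_by_contig):
        nlr_idx = np.flatnonzero(mask)
        for a, b in _linked_runs(starts, ends, nlr_idx, params):
            total += b - a + 1  # run (a, b) spans NLRs a..b inclusive
    return total


def _contig_arrays(genes: pd.DataFrame):
    starts_l, ends_l, masks_l = [], [], []
    for _, sub in genes.groupby("contig", sort=True):
        starts_l.append(sub["start"].to_numpy())
        ends_l.append(sub["end"].to_numpy())
        masks_l.append(sub["is_nlr"].to_numpy(dtype=bool))
    return starts_l, ends_l, masks_l


def permutation_null(
    genes: pd.DataFrame,
    params: ClusterParams = ClusterParams(),
    n_perm: int = 1000,
    seed: int = 0,
) -> PermutationNullSummary:
    """Clustered-gene counts for random NLR relabelings.

    Each replicate draws, uniformly without replacement over all genes, a
    subset of the same size as the observed NLR set, flags it as NLR, and
    recounts clustered genes.  Deterministic under ``seed``.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    genes = _validate_genes(genes)
    n_genes = len(genes)
    n_nlr = int(genes["is_nlr"].sum())
    if n_nlr > n_genes:
        raise ValueError("more NLRs than genes")
    starts_l, ends_l, masks_l = _contig_arrays(genes)
    observed = _count_clustered_mask(starts_l, ends_l, masks_l, params)
    sizes = [len(s) for s in starts_l]
    offsets = np.cumsum([0] + sizes)
    rng = np.random.default_rng(seed)
    counts = np.empty(n_perm, dtype=int)
    for r in range(n_perm):
        chosen = rng.choice(n_genes, size=n_nlr, replace=False)
        flat = np.zeros(n_genes, dtype=bool)
        flat[chosen] = True
        masks = [flat[offsets[i] : offsets[i + 1]] for i in range(len(sizes))]
        counts[r] = _count_clustered_mask(starts_l, ends_l, masks, params)
    return PermutationNullSummary(
        observed=observed,
        mean=float(counts.mean()),
        sd=float(counts.std(ddof=1)) if n_perm > 1 else 0.0,
        counts=counts,
    )


def calibrate_params(
    genomes: Sequence[pd.DataFrame],
    gap_grid: Sequence[int] = DEFAULT_GAP_GRID_BP,
    intervening_grid: Sequence[int] = DEFAULT_INTERVENING_GRID,
    n_perm: int = 1000,
    seed: int = 0,
) -> tuple[ClusterParams, pd.DataFrame]:
    """Select cluster parameters by the shared-argmax rule.

    For every genome and grid point, excess = observed clustered count minus
    the permutation-null mean.  A grid point's score is the fraction of
    genomes at which it attains that genome's maximal excess; the point with
    the highest score wins, ties resolved toward the smaller gap, then the
    smaller intervening count.  Returns the winning parameters and the
    per-genome excess table (columns genome, max_gap_bp, max_intervening,
    observed, null_mean, excess).
    """
    if not len(genomes):
        raise ValueError("empty genome list")
    if not len(gap_grid) or not len(intervening_grid):
        raise ValueError("empty calibration grid")
    rng = np.random.default_rng(seed)
    rows = []
    for g_idx, genes in enumerate(genomes):
        genes = _validate_genes(genes)
        starts_l, ends_l, masks_l = _contig_arrays(genes)
        n_genes = len(genes)
        n_nlr = int(genes["is_nlr"].sum())
        sizes = [len(s) for s in starts_l]
        offsets = np.cumsum([0] + sizes)
        # one set of permutations shared across the grid, per genome
        perms = []
        for _ in range(n_perm):
            flat = np.zeros(n_genes, dtype=bool)
            flat[rng.choice(n_genes, size=n_nlr, replace=False)] = True
            perms.append([flat[offsets[i] : offsets[i + 1]] for i in range(len(sizes))])
        for gap in gap_grid:
            for interv in intervening_grid:
                params = ClusterParams(gap, interv)
                obs = _count_clustered_mask(starts_l, ends_l, masks_l, params)
                null = np.mean(
                    [_count_clustered_mask(starts_l, ends_l, m, params) for m in perms]
                )
                rows.append((g_idx, gap, interv, obs, float(null), obs - float(null)))
    table = pd.DataFrame(
        rows,
        columns=["genome", "max_gap_bp", "max_intervening", "observed", "null_mean", "excess"],
    )
    # score each grid point: fraction of genomes where it reaches the genome max
    per_genome_max = table.groupby("genome")["excess"].transform("max")
    at_max = table[np.isclose(table["excess"], per_genome_max)]
    score = (
        at_max.groupby(["max_gap_bp", "max_intervening"])["genome"]
        .nunique()
        .reindex(
            pd.MultiIndex.from_product(
                [gap_grid, intervening_grid], names=["max_gap_bp", "max_intervening"]
            ),
            fill_value=0,
        )
        / len(genomes)
    )
    best_score = score.max()
    winners = sorted(idx for idx, s in score.items() if s == best_score)
    gap, interv = winners[0]  # smaller gap, then smaller intervening
    return ClusterParams(int(gap), int(interv)), table
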