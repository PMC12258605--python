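"""Synthetic inputs with the statistical structure the pipeline assumes.

Every downstream stage (domain resolution, NLR calling, NB typing,
alignment-free ordination, cluster detection, PGLS) is exercised on data
generated here: per-genome gene tables with planted NLR clusters and
head-to-head pairs, protein sequences with planted Walker A / Walker B /
HETHS motifs of a chosen NB type, domain-hit tables with log-uniform
E-values, and Brownian-motion trait data on a tree with a configurable
linear effect.  All generators are deterministic under their seed.

Planted gene-table structure is recoverable exactly: distinct NLR groups
(clusters, head-to-head pairs, isolated NLRs) are separated by more
intervening genes than the largest intervening-count threshold on the
calibration grid, so no spurious merges occur at the default detection
parameters.  Protein backgrounds are redrawn until no unintended motif match
remains, so typing errors can only come from the classifier, never from
background noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd

from .cluster_genomics import GENE_COLUMNS
from .comparative_stats import phylo_covariance
from .nb_typing import (
    HETHS_NAIP,
    HYDROPHOBIC,
    WALKER_A,
    WALKER_B_NACHT,
    WALKER_B_NBARC,
    DegenerateMotif,
    match_motif,
)

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: TLP1-like HETHS block planted in T-NACHT proteins; its fixed R/D core
#: cannot satisfy the NAIP-like Q-E core, so it never reads as N-NACHT.
HETHS_TLP1 = DegenerateMotif("hhHxxhRDhhxG")

#: Non-NLR groups planted closer than this many intervening genes could merge
#: at the widest calibration grid point (8); one more keeps them separate.
_ISOLATION_GENES = 9


# ---------------------------------------------------------------------------
# gene tables


@dataclass(frozen=True)
class SyntheticGenomeSpec:
    """Layout of one synthetic genome (sizes scaled down from real fungal
    assemblies: ~1-3 kb genes, dense intergenic spacing)."""

    n_contigs: int = 10
    genes_per_contig: int = 150
    gene_length_range: tuple[int, int] = (1_200, 3_000)
    intergenic_gap_range: tuple[int, int] = (200, 3_000)
    n_nlr: int = 20
    n_planted_clusters: int = 3
    cluster_size_range: tuple[int, int] = (2, 4)
    within_cluster_gap_bp: int = 20_000
    within_cluster_intervening: int = 2
    n_head_to_head: int = 1
    seed: int = 0

    def __post_init__(self):
        for name in ("gene_length_range", "intergenic_gap_range", "cluster_size_range"):
            lo, hi = getattr(self, name)
            if lo > hi or lo < (1 if name != "intergenic_gap_range" else 0):
                raise ValueError(f"invalid {name}: ({lo}, {hi})")
        if min(self.n_contigs, self.genes_per_contig) < 1:
            raise ValueError("need at least one contig and one gene per contig")
        if min(self.n_nlr, self.n_planted_clusters, self.n_head_to_head) < 0:
            raise ValueError("counts must be non-negative")
        if self.within_cluster_gap_bp < 0 or self.within_cluster_intervening < 0:
            raise ValueError("within-cluster parameters must be non-negative")


def generate_gene_table(spec: SyntheticGenomeSpec) -> pd.DataFrame:
    """Gene table (1-based inclusive coordinates) with planted NLR structure.

    Planted clusters satisfy the cluster definition at the default detection
    parameters (40 kb, 8 intervening genes); head-to-head pairs are planted
    as additional adjacent divergent (-,+) NLR pairs, i.e. additional size-2
    clusters, so the total planted cluster count is
    ``n_planted_clusters + n_head_to_head``.
    """
    rng = np.random.default_rng(spec.seed)
    sizes = [
        int(rng.integers(spec.cluster_size_range[0], spec.cluster_size_range[1] + 1))
        for _ in range(spec.n_planted_clusters)
    ]
    clustered = sum(sizes) + 2 * spec.n_head_to_head
    if clustered > spec.n_nlr:
        raise ValueError(
            f"spec infeasible: {clustered} clustered NLRs exceed n_nlr={spec.n_nlr}"
        )
    n_singles = spec.n_nlr - clustered

    w = spec.within_cluster_intervening
    min_len = spec.gene_length_range[0]
    if any(s >= 2 for s in sizes) or spec.n_head_to_head:
        needed = w * min_len + (w + 1)
        if needed > spec.within_cluster_gap_bp:
            raise ValueError(
                "spec infeasible: within_cluster_gap_bp too small for "
                f"{w} intervening genes of >= {min_len} bp"
            )

    # groups: ("cluster", size, intervening) | ("h2h",) | ("single",)
    groups: list[tuple] = [("cluster", s) for s in sizes]
    groups += [("h2h",)] * spec.n_head_to_head
    groups += [("single",)] * n_singles
    rng.shuffle(groups)

    # slot plan per contig: None for background genes, group tags for NLRs
    def block_slots(group):
        if group[0] == "cluster":
            # the first member sits on the plus strand so a size-2 planted
            # cluster can never read as an (unplanned) head-to-head pair
            slots = ["nlr_plus"]
            for _ in range(group[1] - 1):
                slots += ["intervening"] * w
                slots.append("nlr")
            return slots
        if group[0] == "h2h":
            return ["h2h_up", "h2h_down"]
        return ["nlr"]

    capacity = spec.n_contigs * spec.genes_per_contig
    plans = [["bg"] * spec.genes_per_contig for _ in range(spec.n_contigs)]
    contig_cursor = [int(rng.integers(0, max(1, spec.genes_per_contig // 4)))
                     for _ in range(spec.n_contigs)]
    order = list(rng.permutation(spec.n_contigs))
    oi = 0
    for group in groups:
        slots = block_slots(group)
        placed = False
        for _ in range(spec.n_contigs):
            c = order[oi % spec.n_contigs]
            oi += 1
            cur = contig_cursor[c]
            if cur + len(slots) <= spec.genes_per_contig:
                plans[c][cur : cur + len(slots)] = slots
                contig_cursor[c] = cur + len(slots) + _ISOLATION_GENES
                placed = True
                break
        if not placed:
            raise ValueError(
                f"spec infeasible: cannot place NLR groups in {capacity} gene slots"
            )

    # coordinates: within cluster blocks, clamp spacing so consecutive NLRs
    # sit within within_cluster_gap_bp of each other
    gap_w = max(1, (spec.within_cluster_gap_bp - w * min_len) // (w + 1))
    gap_w = min(gap_w, spec.intergenic_gap_range[1])
    rows = []
    for c in range(spec.n_contigs):
        contig = f"contig_{c + 1}"
        pos = 1
        for g, slot in enumerate(plans[c]):
            # a clamped gap precedes any gene whose predecessor belongs to
            # the same cluster block, keeping inter-NLR spans within budget
            in_block = slot in ("intervening", "h2h_down") or (
                slot == "nlr"
                and g > 0
                and plans[c][g - 1] in ("nlr", "nlr_plus", "intervening")
            )
            if g > 0:
                pos += gap_w if in_block else int(
                    rng.integers(spec.intergenic_gap_range[0], spec.intergenic_gap_range[1] + 1)
                )
            length = min_len if slot == "intervening" else int(
                rng.integers(spec.gene_length_range[0], spec.gene_length_range[1] + 1)
            )
            if slot == "h2h_up":
                strand = "-"
            elif slot in ("h2h_down", "nlr_plus"):
                strand = "+"
            else:
                strand = "+" if rng.random() < 0.5 else "-"
            is_nlr = slot in ("nlr", "nlr_plus", "h2h_up", "h2h_down")
            rows.append(
                (f"{contig}_g{g + 1:04d}", contig, pos, pos + length - 1, strand, is_nlr)
            )
            pos += length
    return pd.DataFrame(rows, columns=GENE_COLUMNS)


# ---------------------------------------------------------------------------
# proteins


@dataclass(frozen=True)
class SyntheticProteinSpec:
    """Layout of one synthetic NB-domain protein (1-based motif offsets)."""

    nb_type: str = "T-NACHT"  # "T-NACHT" | "N-NACHT" | "NB-ARC"
    total_length: int = 350
    walkerA_pos: int = 40
    walkerB_pos: int = 120
    heths_pos: int = 220
    background_alphabet: str = AMINO_ACIDS
    corrupt_motif: bool | str = False  # False | True ("walker_b") | motif name
    seed: int = 0

    def __post_init__(self):
        if self.nb_type not in ("T-NACHT", "N-NACHT", "NB-ARC"):
            raise ValueError(f"unknown nb_type {self.nb_type!r}")
        if not 1 <= self.walkerA_pos < self.walkerB_pos < self.heths_pos <= self.total_length:
            raise ValueError("motif positions must satisfy walkerA < walkerB < heths <= length")
        windows = [
            (self.walkerA_pos, self.walkerA_pos + len(WALKER_A) - 1),
            (self.walkerB_pos, self.walkerB_pos + len(WALKER_B_NACHT) - 1),
            (self.heths_pos, self.heths_pos + len(HETHS_NAIP) - 1),
        ]
        for (s1, e1), (s2, e2) in zip(windows, windows[1:]):
            if e1 >= s2:
                raise ValueError("motif windows overlap")
        if windows[-1][1] > self.total_length:
            raise ValueError("motifs do not fit in total_length")
        if not self.background_alphabet:
            raise ValueError("empty background alphabet")


def _instantiate(motif: DegenerateMotif, rng: np.random.Generator) -> str:
    out = []
    for allowed in motif.positions:
        residues = AMINO_ACIDS if allowed is None else "".join(sorted(allowed))
        out.append(residues[rng.integers(0, len(residues))])
    return "".join(out)


def _planted_windows(spec: SyntheticProteinSpec) -> dict[str, tuple[int, DegenerateMotif]]:
    """Motif name -> (0-based offset, motif) for the planted instances."""
    windows = {"walker_a": (spec.walkerA_pos - 1, WALKER_A)}
    if spec.nb_type == "NB-ARC":
        windows["walker_b"] = (spec.walkerB_pos - 1, WALKER_B_NBARC)
    else:
        windows["walker_b"] = (spec.walkerB_pos - 1, WALKER_B_NACHT)
        windows["heths"] = (
            spec.heths_pos - 1,
            HETHS_NAIP if spec.nb_type == "N-NACHT" else HETHS_TLP1,
        )
    return windows


def _unintended_match(seq: str, spec: SyntheticProteinSpec) -> bool:
    """Any Walker B or NAIP-HETHS match outside its planted position."""
    wb_off = spec.walkerB_pos - 1
    for motif in (WALKER_B_NACHT, WALKER_B_NBARC):
        for m in match_motif(seq, motif):
            if m.aa_start - 1 != wb_off:
                return True
    naip_off = spec.heths_pos - 1 if spec.nb_type == "N-NACHT" else None
    for m in match_motif(seq, HETHS_NAIP):
        if m.aa_start - 1 != naip_off:
            return True
    return False


def generate_nb_protein(spec: SyntheticProteinSpec) -> str:
    """A protein with the chosen NB type's motifs at the stated offsets.

    The background is uniform over ``background_alphabet`` and redrawn until
    no unintended Walker B / NAIP-HETHS match exists, so the planted motifs
    are the only diagnostic signal.  With ``corrupt_motif`` set, exactly one
    position of the named planted motif (default Walker B) is mutated to a
    residue that breaks the match.
    """
    rng = np.random.default_rng(spec.seed)
    windows = _planted_windows(spec)
    planted = {name: (off, _instantiate(motif, rng)) for name, (off, motif) in windows.items()}
    alphabet = list(spec.background_alphabet)
    for _ in range(200):
        residues = [alphabet[i] for i in rng.integers(0, len(alphabet), spec.total_length)]
        for off, inst in planted.values():
            residues[off : off + len(inst)] = inst
        seq = "".join(residues)
        if not _unintended_match(seq, spec):
            break
    else:  # pragma: no cover - would need an adversarial alphabet
        raise RuntimeError("could not draw a background free of spurious motifs")

    if spec.corrupt_motif:
        name = "walker_b" if spec.corrupt_motif is True else str(spec.corrupt_motif)
        if name not in planted:
            raise ValueError(f"no planted motif {name!r} for nb_type {spec.nb_type}")
        off, inst = planted[name]
        # proline is outside every motif class used here (not hydrophobic,
        # not acidic, not G/A/S, and not a literal of any planted motif)
        target = 4 if name == "walker_b" else 0  # the diagnostic D / leading F/G
        residues = list(seq)
        residues[off + target] = "P"
        seq = "".join(residues)
    return seq


# ---------------------------------------------------------------------------
# NB fragment families for ordination


def generate_nb_fragment_set(
    counts: Mapping[str, int] | None = None,
    length: int = 350,
    divergence: float = 0.2,
    seed: int = 0,
) -> tuple[dict[str, str], dict[str, str]]:
    """Families of fragment-2 sequences (Walker B start to C-terminus).

    One template protein per NB type is generated, its second fragment taken,
    and each family member derived from the template by substituting
    non-motif positions independently with probability ``divergence``
    (uniform replacement).  Members of one type therefore share the type's
    motif blocks and ~(1 - divergence) background identity, while types are
    unrelated — the structure of diverged homologous NB families.

    Returns (sequences, type_of) keyed by sequence label.
    """
    if counts is None:
        counts = {"T-NACHT": 50, "NB-ARC": 20, "N-NACHT": 4}
    if not 0.0 <= divergence < 1.0:
        raise ValueError("divergence must be in [0, 1)")
    rng = np.random.default_rng(seed)
    seqs: dict[str, str] = {}
    type_of: dict[str, str] = {}
    for t_idx, (nb_type, n) in enumerate(sorted(counts.items())):
        spec = SyntheticProteinSpec(
            nb_type=nb_type, total_length=length, seed=int(rng.integers(2**31))
        )
        template = generate_nb_protein(spec)
        frag2 = template[spec.walkerB_pos - 1 :]
        # 0-based positions (within fragment 2) that carry planted motifs
        protected = set()
        for name, (off, motif) in _planted_windows(spec).items():
            if name == "walker_a":
                continue
            for k in range(len(motif)):
                protected.add(off + k - (spec.walkerB_pos - 1))
        for i in range(n):
            member = list(frag2)
            for p in range(len(member)):
                if p in protected:
                    continue
                if rng.random() < divergence:
                    member[p] = AMINO_ACIDS[rng.integers(0, len(AMINO_ACIDS))]
            label = f"{nb_type}_{i + 1:03d}"
            seqs[label] = "".join(member)
            type_of[label] = nb_type
    return seqs, type_of


# ---------------------------------------------------------------------------
# domain-hit tables


def generate_domain_hits(
    gene_table: pd.DataFrame,
    architecture_plan: Mapping[str, Sequence[tuple]],
    seed: int = 0,
    evalue_range: tuple[float, float] = (1e-30, 1e-4),
) -> pd.DataFrame:
    """Domain-hit table for a plan of per-gene architectures.

    ``architecture_plan`` maps gene id to a list of
    ``(profile, source, (aa_start, aa_end))`` tuples, optionally with a
    fourth element fixing the E-value (decoy hits with controlled ratios).
    Free E-values are drawn log-uniform over ``evalue_range``.
    """
    from .domain_annotation import HIT_COLUMNS

    rng = np.random.default_rng(seed)
    known = set(gene_table["gene_id"]) if gene_table is not None and len(gene_table) else None
    lo, hi = np.log10(evalue_range[0]), np.log10(evalue_range[1])
    rows = []
    for gene_id in sorted(architecture_plan):
        if known is not None and gene_id not in known:
            raise KeyError(f"plan references unknown gene {gene_id}")
        for entry in architecture_plan[gene_id]:
            profile, source, (aa_start, aa_end) = entry[:3]
            if aa_start < 1 or aa_start > aa_end:
                raise ValueError(f"bad region for {gene_id}/{profile}")
            evalue = float(entry[3]) if len(entry) > 3 else float(10 ** rng.uniform(lo, hi))
            score = float(-10.0 * np.log10(evalue) + rng.normal(0, 2))
            rows.append((gene_id, profile, source, int(aa_start), int(aa_end), evalue, score))
    return pd.DataFrame(rows, columns=HIT_COLUMNS)


# ---------------------------------------------------------------------------
# trees and traits


def generate_tree(n_tips: int, seed: int = 0, birth_rate: float = 1.0) -> dendropy.Tree:
    """A random pure-birth tree with ``n_tips`` leaves (labels t1..tN)."""
    import random as _random

    from dendropy.model import birthdeath

    rng = _random.Random(seed)
    tree = birthdeath.birth_death_tree(
        birth_rate=birth_rate,
        death_rate=0.0,
        num_extant_tips=n_tips,
        rng=rng,
    )
    for i, leaf in enumerate(tree.leaf_node_iter(), start=1):
        leaf.taxon.label = f"t{i}"
    return tree


def generate_brownian_traits(
    tree: dendropy.Tree,
    slope: float = 2.0,
    intercept: float = 1.0,
    sigma2: float = 1.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Tip traits with a linear effect and Brownian phylogenetic residuals.

    x is standard normal, independent per tip; y = intercept + slope * x + e
    with e multivariate normal of covariance ``sigma2 *`` shared-branch-length
    matrix.  Returns a table with columns ``taxon, x, y``.
    """
    if sigma2 < 0:
        raise ValueError("sigma2 must be non-negative")
    c, taxa = phylo_covariance(tree)  # raises on zero-depth trees
    rng = np.random.default_rng(seed)
    n = len(taxa)
    x = rng.standard_normal(n)
    if sigma2 > 0:
        # C is PSD; tiny jitter keeps Cholesky stable on near-singular trees
        chol = np.linalg.cholesky(sigma2 * c + 1e-12 * np.eye(n))
        e = chol @ rng.standard_normal(n)
    else:
        e = np.zeros(n)
    y = intercept + slope * x + e
    return pd.DataFrame({"taxon": taxa, "x": x, "y": y})
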