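"""Cluster detection, permutation null, calibration, head-to-head pairs."""

import numpy as np
import pandas as pd
import pytest
from conftest import brute_force_clusters, random_gene_table

from nlrscape.cluster_genomics import (
    GENE_COLUMNS,
    ClusterParams,
    calibrate_params,
    count_clustered,
    detect_clusters,
    detect_head_to_head,
    permutation_null,
)
from nlrscape.synthetic_data import SyntheticGenomeSpec, generate_gene_table


def table_from(rows):
    return pd.DataFrame(rows, columns=GENE_COLUMNS)


def nlr_pair(gap_bp, intervening=0, strands=("+", "+")):
    """Two NLRs separated by `gap_bp` and `intervening` evenly spaced non-NLR
    genes on one contig."""
    rows = [("n1", "c1", 1, 1000, strands[0], True)]
    pos = 1001
    if intervening:
        slot = gap_bp // (intervening + 1)
        for i in range(intervening):
            start = pos + (i + 1) * slot - 200
            rows.append((f"x{i}", "c1", start, start + 99, "+", False))
    rows.append(("n2", "c1", 1000 + gap_bp + 1, 1000 + gap_bp + 1000, strands[1], True))
    return table_from(rows)


class TestDetectClusters:
    def test_linked_then_broken_run(self):
        # gaps 10 kb then 50 kb: only the first pair clusters
        rows = [
            ("n1", "c1", 1, 1000, "+", True),
            ("n2", "c1", 11_002, 12_001, "+", True),
            ("n3", "c1", 62_003, 63_002, "+", True),
        ]
        clusters = detect_clusters(table_from(rows), ClusterParams(40_000, 8))
        assert [c.members for c in clusters] == [("n1", "n2")]

    def test_single_nlr_never_clusters(self):
        rows = [("n1", "c1", 1, 1000, "+", True), ("x1", "c1", 2000, 2500, "+", False)]
        assert detect_clusters(table_from(rows)) == []

    def test_intervening_count_vetoes_despite_small_gap(self):
        genes = nlr_pair(gap_bp=5000, intervening=9)
        assert detect_clusters(genes, ClusterParams(40_000, 8)) == []
        assert detect_clusters(genes, ClusterParams(40_000, 9)) != []

    def test_inclusive_thresholds_and_strict_mode(self):
        genes = nlr_pair(gap_bp=40_000)
        assert len(detect_clusters(genes, ClusterParams(40_000, 8))) == 1
        assert detect_clusters(genes, ClusterParams(40_000, 8, strict=True)) == []

    def test_clusters_never_span_contigs(self):
        rows = [
            ("n1", "c1", 1, 1000, "+", True),
            ("n2", "c2", 1500, 2500, "+", True),
        ]
        assert detect_clusters(table_from(rows)) == []

    def test_overlapping_nlr_genes_treated_as_zero_gap(self):
        rows = [
            ("n1", "c1", 1, 2000, "+", True),
            ("n2", "c1", 1500, 3000, "+", True),
        ]
        clusters = detect_clusters(table_from(rows), ClusterParams(0, 0))
        assert len(clusters) == 1

    def test_agrees_with_brute_force_oracle(self):
        """Exhaustive-run enumeration on 200 random small tables."""
        rng = np.random.default_rng(0)
        for trial in range(200):
            genes = random_gene_table(rng, n_genes=int(rng.integers(4, 50)))
            params = ClusterParams(
                int(rng.choice([5_000, 20_000, 40_000])), int(rng.integers(0, 4))
            )
            ours = [c.members for c in detect_clusters(genes, params)]
            assert ours == brute_force_clusters(genes, params), f"trial {trial}"

    def test_membership_partitions_clustered_nlrs(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            genes = random_gene_table(rng, n_genes=40)
            clusters = detect_clusters(genes, ClusterParams(30_000, 3))
            seen = [m for c in clusters for m in c.members]
            assert len(seen) == len(set(seen))


class TestCountClustered:
    def test_empty_and_simple_counts(self):
        assert count_clustered(table_from([])) == 0
        rows = [
            ("n1", "c1", 1, 1000, "+", True),
            ("n2", "c1", 2001, 3000, "+", True),
            ("n3", "c1", 4001, 5000, "+", True),
            ("n4", "c1", 900_000, 901_000, "+", True),
        ]
        assert count_clustered(table_from(rows), ClusterParams(40_000, 8)) == 3

    def test_monotone_in_both_parameters(self):
        rng = np.random.default_rng(2)
        for _ in range(100):
            genes = random_gene_table(rng, n_genes=30)
            gaps = [0, 10_000, 40_000, 200_000]
            counts_gap = [count_clustered(genes, ClusterParams(g, 3)) for g in gaps]
            assert all(a <= b for a, b in zip(counts_gap, counts_gap[1:]))
            intervs = [0, 2, 5, 8]
            counts_int = [count_clustered(genes, ClusterParams(30_000, i)) for i in intervs]
            assert all(a <= b for a, b in zip(counts_int, counts_int[1:]))


class TestPermutationNull:
    def test_all_genes_nlr_forces_observed_count(self):
        rows = [
            (f"n{i}", "c1", 1 + i * 2000, 1000 + i * 2000, "+", True) for i in range(6)
        ]
        genes = table_from(rows)
        summary = permutation_null(genes, ClusterParams(40_000, 8), n_perm=20, seed=0)
        assert summary.observed == 6
        assert np.all(summary.counts == 6)
        assert summary.mean == 6.0

    def test_determinism_under_seed(self):
        rng = np.random.default_rng(3)
        genes = random_gene_table(rng, n_genes=40)
        a = permutation_null(genes, n_perm=200, seed=7)
        b = permutation_null(genes, n_perm=200, seed=7)
        assert np.array_equal(a.counts, b.counts)

    def test_planted_cluster_exceeds_null(self):
        """A genome with one tight planted cluster among dispersed genes
        shows observed > null mean in nearly all seeded runs."""
        spec = SyntheticGenomeSpec(
            n_contigs=4, genes_per_contig=80, n_nlr=6, n_planted_clusters=1,
            cluster_size_range=(4, 4), n_head_to_head=0, seed=0,
        )
        genes = generate_gene_table(spec)
        wins = 0
        for s in range(100):
            summary = permutation_null(genes, n_perm=30, seed=s)
            if summary.observed > summary.mean:
                wins += 1
        assert wins >= 95

    def test_replicate_counts_exchangeable_across_seeds(self):
        from scipy import stats

        rng = np.random.default_rng(4)
        genes = random_gene_table(rng, n_genes=60, p_nlr=0.25)
        not_rejected = 0
        trials = 5
        for t in range(trials):
            a = permutation_null(genes, n_perm=300, seed=10 + t).counts
            b = permutation_null(genes, n_perm=300, seed=900 + t).counts
            if stats.ks_2samp(a, b).pvalue > 0.01:
                not_rejected += 1
        assert not_rejected >= trials - 1

    def test_invalid_replicate_count_rejected(self):
        genes = table_from([("n1", "c1", 1, 1000, "+", True)])
        permutation_null(genes, n_perm=1, seed=0)  # degenerate but valid
        with pytest.raises(ValueError):
            permutation_null(genes, n_perm=0, seed=0)


class TestCalibration:
    def test_grid_point_with_unique_max_selected(self):
        # one genome whose excess is uniquely maximal at the planted scale
        spec = SyntheticGenomeSpec(
            n_contigs=4, genes_per_contig=60, n_nlr=8, n_planted_clusters=2,
            cluster_size_range=(3, 3), within_cluster_gap_bp=8_000,
            within_cluster_intervening=1, n_head_to_head=0, seed=5,
        )
        genes = generate_gene_table(spec)
        params, table = calibrate_params(
            [genes], gap_grid=[1_000, 10_000, 40_000, 200_000],
            intervening_grid=[0, 1, 2, 8], n_perm=60, seed=0,
        )
        # planted clusters sit within 8 kb spans with one intervening gene:
        # the selected gap must be large enough to capture them and the
        # selected intervening count at least one
        assert params.max_gap_bp in (10_000, 40_000)
        assert params.max_intervening >= 1
        assert len(table) == 16

    def test_tie_breaks_toward_smaller_parameters(self):
        # a genome with NO NLRs at all: every grid point has excess 0, so the
        # tie rule must pick the smallest gap, then smallest intervening count
        spec = SyntheticGenomeSpec(n_nlr=0, n_planted_clusters=0, n_head_to_head=0, seed=1)
        genes = generate_gene_table(spec)
        params, _ = calibrate_params(
            [genes], gap_grid=[5_000, 10_000], intervening_grid=[0, 1],
            n_perm=5, seed=0,
        )
        assert (params.max_gap_bp, params.max_intervening) == (5_000, 0)

    def test_empty_genome_list_rejected(self):
        with pytest.raises(ValueError):
            calibrate_params([], n_perm=5, seed=0)


class TestHeadToHead:
    @pytest.mark.parametrize(
        "strands,expected",
        [(("-", "+"), True), (("+", "+"), False), (("+", "-"), False), (("-", "-"), False)],
    )
    def test_orientation_rule(self, strands, expected):
        genes = nlr_pair(gap_bp=2_000, strands=strands)
        clusters = detect_clusters(genes, ClusterParams(40_000, 8))
        assert len(clusters) == 1
        assert clusters[0].head_to_head is expected
        assert detect_head_to_head(clusters[0], genes) is expected

    def test_larger_clusters_not_applicable(self):
        rows = [
            ("n1", "c1", 1, 1000, "-", True),
            ("n2", "c1", 2001, 3000, "+", True),
            ("n3", "c1", 4001, 5000, "+", True),
        ]
        genes = table_from(rows)
        (cluster,) = detect_clusters(genes, ClusterParams(40_000, 8))
        assert len(cluster) == 3
        assert detect_head_to_head(cluster, genes) is False
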