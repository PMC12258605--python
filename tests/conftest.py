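"""Shared fixtures and independent oracle implementations.

The oracles here deliberately re-derive results by brute force (exhaustive
enumeration, substring search, covered-position unions) so the tests compare
two independent routes to the same answer.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from nlrscape.cluster_genomics import ClusterParams, GENE_COLUMNS


# ---------------------------------------------------------------------------
# brute-force oracles


def brute_force_clusters(genes: pd.DataFrame, params: ClusterParams) -> list[tuple[str, ...]]:
    """Enumerate every contiguous NLR run per contig and keep the maximal
    ones whose consecutive pairs all satisfy the parameters."""
    out = []
    for contig, sub in genes.sort_values(["contig", "start"]).groupby("contig", sort=True):
        sub = sub.reset_index(drop=True)
        nlr_pos = [i for i in range(len(sub)) if sub.loc[i, "is_nlr"]]

        def pair_ok(i, j):  # consecutive NLRs at table rows i < j
            gap = max(sub.loc[j, "start"] - sub.loc[i, "end"] - 1, 0)
            intervening = sum(
                1 for k in range(i + 1, j) if not sub.loc[k, "is_nlr"]
            )
            if params.strict:
                return gap < params.max_gap_bp and intervening < params.max_intervening
            return gap <= params.max_gap_bp and intervening <= params.max_intervening

        runs = []
        for a in range(len(nlr_pos)):
            for b in range(a + 1, len(nlr_pos)):
                if all(
                    pair_ok(nlr_pos[k], nlr_pos[k + 1]) for k in range(a, b)
                ):
                    runs.append((a, b))
        maximal = [
            (a, b)
            for a, b in runs
            if not any((c <= a and b <= d and (c, d) != (a, b)) for c, d in runs)
        ]
        for a, b in sorted(maximal):
            out.append(tuple(sub.loc[nlr_pos[a : b + 1], "gene_id"]))
    return out


def lz76_oracle(s: str) -> int:
    """Production count via the definition: each component is the longest
    prefix of the remainder reproducible from the preceding history, plus
    one innovative symbol."""
    n = len(s)
    c, i = 0, 0
    while i < n:
        l = 1
        while i + l <= n and s[i : i + l] in s[: i + l - 1]:
            l += 1
        c += 1
        i += l
    return c


def merge_intervals_oracle(intervals):
    """Union of covered integer positions, re-chunked into runs."""
    covered = sorted({p for s, e in intervals for p in range(s, e + 1)})
    out = []
    for p in covered:
        if out and p == out[-1][1] + 1:
            out[-1][1] = p
        else:
            out.append([p, p])
    return [tuple(iv) for iv in out]


def plateau_oracle(inflations, counts):
    """Scan every window of length 3 for the earliest constant one."""
    for i in range(len(counts) - 2):
        if len(set(counts[i : i + 3])) == 1:
            return inflations[i]
    return None


def random_gene_table(rng: np.random.Generator, n_genes: int, p_nlr: float = 0.3,
                      n_contigs: int = 2) -> pd.DataFrame:
    """A random (structure-free) gene table for property tests."""
    rows = []
    for c in range(n_contigs):
        pos = 1
        for g in range(n_genes // n_contigs):
            length = int(rng.integers(500, 3000))
            rows.append(
                (
                    f"c{c}_g{g}",
                    f"c{c}",
                    pos,
                    pos + length - 1,
                    "+" if rng.random() < 0.5 else "-",
                    bool(rng.random() < p_nlr),
                )
            )
            pos += length + int(rng.integers(0, 30000))
    return pd.DataFrame(rows, columns=GENE_COLUMNS)


@pytest.fixture(scope="session")
def star_tree():
    """Eight tips hanging directly off the root, all at depth 1."""
    import dendropy

    newick = "(" + ",".join(f"t{i}:1.0" for i in range(1, 9)) + ");"
    return dendropy.Tree.get(data=newick, schema="newick")
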