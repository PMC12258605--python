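"""Phylogenetically corrected regression and repertoire summaries.

NLR counts covary across taxa because related species inherit similar
repertoires; phylogenetic generalized least squares (PGLS) corrects ordinary
regression by giving residuals a covariance proportional to shared
root-to-tip branch length under Brownian motion, with the off-diagonals
scaled by Pagel's lambda (0 = star phylogeny / ordinary least squares,
1 = pure Brownian).  Lambda is estimated by maximum likelihood on [0, 1].

The module also provides the Markov-clustering inflation selector (first
value of the earliest run of three consecutive equal NLR counts) and the
repertoire summary tables (shares per NB type and per terminal-domain
category, and the realized fraction of possible domain combinations).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.linalg import solve_triangular

__all__ = [
    "PGLSFit",
    "phylo_covariance",
    "brownian_vcv",
    "pgls_fit",
    "plateau_select_inflation",
    "summarize_repertoire",
    "combination_space",
    "CombinationSpace",
    "round_half_away",
]


@dataclass(frozen=True)
class PGLSFit:
    slope: float
    intercept: float
    lam: float
    adj_r2: float
    p_value: float
    n: int
    log_likelihood: float


def phylo_covariance(tree: dendropy.Tree) -> tuple[np.ndarray, list[str]]:
    """Shared root-to-tip branch-length matrix C (Brownian covariance up to
    sigma^2) and the taxon labels in matrix order."""
    taxa = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    n = len(taxa)
    depth = {}
    for node in tree.preorder_node_iter():
        edge = node.edge.length or 0.0
        if edge < 0:
            raise ValueError("negative branch length")
        depth[node] = (depth[node.parent_node] if node.parent_node else 0.0) + edge
    pdm = tree.phylogenetic_distance_matrix()
    leaf_by_label = {leaf.taxon.label: leaf for leaf in tree.leaf_node_iter()}
    c = np.zeros((n, n))
    for i, a in enumerate(taxa):
        c[i, i] = depth[leaf_by_label[a]]
        for j in range(i + 1, n):
            b = taxa[j]
            d = pdm.patristic_distance(leaf_by_label[a].taxon, leaf_by_label[b].taxon)
            shared = (depth[leaf_by_label[a]] + depth[leaf_by_label[b]] - d) / 2.0
            c[i, j] = c[j, i] = max(shared, 0.0)
    if np.all(c == 0):
        raise ValueError("tree has zero total depth")
    return c, taxa


def brownian_vcv(tree: dendropy.Tree, lam: float = 1.0) -> tuple[np.ndarray, list[str]]:
    """Pagel-lambda-transformed Brownian covariance: off-diagonals of the
    shared-branch-length matrix multiplied by ``lam``; diagonals unchanged."""
    if not 0.0 <= lam <= 1.0:
        raise ValueError("lambda must lie in [0, 1]")
    c, taxa = phylo_covariance(tree)
    v = c * lam
    np.fill_diagonal(v, np.diag(c))
    return v, taxa


def _gls(x: np.ndarray, y: np.ndarray, v: np.ndarray):
    """GLS fit of y on [1, x] under covariance v; returns coefficients,
    whitened design/response, residual sum of squares, log|V|."""
    n = len(y)
    # near-zero sister branches make V numerically singular; a relative
    # ridge far below estimation error keeps the factorization stable
    ridge = 1e-10 * float(np.mean(np.diag(v)))
    chol = np.linalg.cholesky(v + ridge * np.eye(n))
    design = np.column_stack([np.ones(n), x])
    xw = solve_triangular(chol, design, lower=True)
    yw = solve_triangular(chol, y, lower=True)
    beta, _, _, _ = np.linalg.lstsq(xw, yw, rcond=None)
    resid = yw - xw @ beta
    rss = float(resid @ resid)
    logdet = 2.0 * float(np.sum(np.log(np.diag(chol))))
    return beta, xw, yw, rss, logdet


def _profile_loglik(x, y, c, lam):
    v = c * lam
    np.fill_diagonal(v, np.diag(c))
    _, _, _, rss, logdet = _gls(x, y, v)
    n = len(y)
    sigma2 = max(rss / n, 1e-300)  # exact fits: keep the log finite
    return -0.5 * (n * math.log(2 * math.pi * sigma2) + logdet + n)


def pgls_fit(
    x: Sequence[float],
    y: Sequence[float],
    tree: dendropy.Tree,
    taxa: Sequence[str] | None = None,
    lam: float | None = None,
) -> PGLSFit:
    """PGLS regression of y on x with ML estimation of Pagel's lambda.

    ``taxa`` gives the taxon order of x and y; defaults to the tree's leaf
    order.  Pass ``lam`` to fix lambda instead of optimizing (lam=0
    reproduces ordinary least squares).  Reports the slope, the adjusted R^2
    computed in the whitened space, and the two-sided t-test p-value of the
    slope (df = n - 2).
    """
    c, tree_taxa = phylo_covariance(tree)
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(y)
    if n < 4:
        raise ValueError("need at least 4 taxa")
    if len(x) != n:
        raise ValueError("x and y length mismatch")
    if taxa is not None:
        order = [list(taxa).index(t) for t in tree_taxa]
        x, y = x[order], y[order]

    if lam is None:
        res = optimize.minimize_scalar(
            lambda l: -_profile_loglik(x, y, c, l),
            bounds=(0.0, 1.0),
            method="bounded",
            options={"xatol": 1e-6},
        )
        lam_hat = float(res.x)
        # the optimum can sit on a boundary the bounded search only approaches
        for cand in (0.0, 1.0):
            if _profile_loglik(x, y, c, cand) > _profile_loglik(x, y, c, lam_hat):
                lam_hat = cand
    else:
        if not 0.0 <= lam <= 1.0:
            raise ValueError("lambda must lie in [0, 1]")
        lam_hat = float(lam)

    v = c * lam_hat
    np.fill_diagonal(v, np.diag(c))
    beta, xw, yw, rss, _ = _gls(x, y, v)
    # total SS about the GLS intercept-only fit, in the whitened space
    ones_w = xw[:, 0]
    mu = float(ones_w @ yw) / float(ones_w @ ones_w)
    tss = float(((yw - mu * ones_w) ** 2).sum())
    r2 = 1.0 - rss / tss if tss > 0 else 1.0
    adj_r2 = 1.0 - (1.0 - r2) * (n - 1) / (n - 2)
    sigma2 = rss / (n - 2)
    cov_beta = sigma2 * np.linalg.inv(xw.T @ xw)
    se_slope = math.sqrt(cov_beta[1, 1])
    if se_slope == 0.0:
        p = 0.0 if beta[1] != 0 else 1.0
    else:
        t_stat = beta[1] / se_slope
        p = 2.0 * stats.t.sf(abs(t_stat), df=n - 2)
    return PGLSFit(
        slope=float(beta[1]),
        intercept=float(beta[0]),
        lam=lam_hat,
        adj_r2=float(adj_r2),
        p_value=float(p),
        n=n,
        log_likelihood=float(_profile_loglik(x, y, c, lam_hat)),
    )


def plateau_select_inflation(table: pd.DataFrame) -> float | None:
    """First inflation value of the earliest run of three consecutive equal
    NLR counts; None when no plateau exists.

    ``table`` needs columns ``inflation`` (strictly increasing) and ``count``.
    """
    if len(table) < 3:
        raise ValueError("need at least three inflation values")
    infl = table["inflation"].to_numpy(dtype=float)
    if not np.all(np.diff(infl) > 0):
        raise ValueError("inflation values must be strictly increasing")
    counts = table["count"].to_numpy()
    for i in range(len(counts) - 2):
        if counts[i] == counts[i + 1] == counts[i + 2]:
            return float(infl[i])
    return None


def round_half_away(x: float, ndigits: int = 0) -> float:
    """Round half away from zero (the convention of the reported shares)."""
    factor = 10**ndigits
    return math.floor(abs(x) * factor + 0.5) / factor * (1 if x >= 0 else -1)


def summarize_repertoire(records: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Counts and shares of a repertoire table.

    ``records`` needs columns ``nb_type``, ``nterm_category``,
    ``cterm_category``.  Returns tables keyed ``nb_type`` (one-decimal
    percentages), ``nterm``, ``cterm``, and the two cross-tabs
    ``nb_by_nterm`` / ``nb_by_cterm`` with integer row percentages.
    """
    out: dict[str, pd.DataFrame] = {}
    if records.empty:
        return {k: pd.DataFrame() for k in ("nb_type", "nterm", "cterm", "nb_by_nterm", "nb_by_cterm")}
    total = len(records)
    for key, col in (("nb_type", "nb_type"), ("nterm", "nterm_category"), ("cterm", "cterm_category")):
        counts = records[col].value_counts()
        out[key] = pd.DataFrame(
            {
                "count": counts,
                "percent": [round_half_away(100.0 * c / total, 1) for c in counts],
            }
        )
    for key, col in (("nb_by_nterm", "nterm_category"), ("nb_by_cterm", "cterm_category")):
        ct = pd.crosstab(records[col], records["nb_type"])
        pct = ct.div(ct.sum(axis=1), axis=0).mul(100.0).map(lambda v: round_half_away(v, 0))
        out[key] = pd.concat({"count": ct, "percent": pct.astype(int)}, axis=1)
    return out


@dataclass(frozen=True)
class CombinationSpace:
    possible_nterm_nb: int
    possible_nb_cterm: int
    possible_tripartite: int
    observed_nterm_nb: int
    observed_nb_cterm: int
    observed_tripartite: int
    realized_tripartite_pct: float


def combination_space(
    n_nterm: int, n_nb: int, n_cterm: int, observed: set[tuple[str, str, str]]
) -> CombinationSpace:
    """Possible vs observed domain-combination counts.

    ``observed`` holds (nterm, nb, cterm) category triples; the pairwise
    observed counts are the distinct projections.
    """
    if min(n_nterm, n_nb, n_cterm) < 1:
        raise ValueError("category counts must be >= 1")
    trip = {t for t in observed}
    nterm_nb = {(a, b) for a, b, _ in trip}
    nb_cterm = {(b, c) for _, b, c in trip}
    possible_trip = n_nterm * n_nb * n_cterm
    return CombinationSpace(
        possible_nterm_nb=n_nterm * n_nb,
        possible_nb_cterm=n_nb * n_cterm,
        possible_tripartite=possible_trip,
        observed_nterm_nb=len(nterm_nb),
        observed_nb_cterm=len(nb_cterm),
        observed_tripartite=len(trip),
        realized_tripartite_pct=round_half_away(100.0 * len(trip) / possible_trip, 1),
    )
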