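"""Alignment-free sequence distances and classical-scaling ordination.

NB-domain fragments of NACHT and NB-ARC NLRs are too diverged for reliable
multiple alignment, so pairwise dissimilarity is measured without aligning:

* normalized Google distance on k-mer *sets* (default k = 3):
  ``d = (|A| + |B| - 2|A∩B|) / (|A| + |B| - |A∩B|)``;
* Lempel–Ziv complexity distance, using the LZ76 exhaustive-history
  production count C(.) in the Otu–Sayood normalized form
  ``d = max{C(xy) - C(x), C(yx) - C(y)} / max{C(x), C(y)}``.

For gap-aligned protein pairs (the protein-kinase decoy comparison) a
BLOSUM62 score-based dissimilarity is provided:
``d = 1 - S12 / max(S11, S22)`` over columns where neither sequence is
gapped.  Distance matrices are embedded with classical principal coordinates
analysis (Torgerson scaling): double-center ``-0.5 * D**2``, eigendecompose,
and scale eigenvectors by the square roots of the positive eigenvalues.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
from Bio.Align import substitution_matrices

__all__ = [
    "DistanceMatrix",
    "PCoAResult",
    "kmer_set",
    "google_distance",
    "lz_complexity",
    "lz_distance",
    "blosum62_distance",
    "pairwise_distance_matrix",
    "pcoa",
]

_BLOSUM62 = substitution_matrices.load("BLOSUM62")
GAP_CHARS = frozenset("-.")


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric non-negative distances with a zero diagonal."""

    labels: tuple
    values: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1] or v.shape[0] != len(self.labels):
            raise ValueError("values must be square and match labels")
        if not np.allclose(v, v.T):
            raise ValueError("distance matrix must be symmetric")
        if not np.all(np.isfinite(v)) or (v < 0).any():
            raise ValueError("distances must be finite and non-negative")
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "labels", tuple(self.labels))

    def __getitem__(self, pair):
        i = self.labels.index(pair[0])
        j = self.labels.index(pair[1])
        return self.values[i, j]


@dataclass(frozen=True)
class PCoAResult:
    """Coordinates (samples x axes) and eigenvalues in non-increasing order.

    Only axes with positive eigenvalues carry coordinates; negative
    eigenvalues (non-Euclidean input) are reported but their axes dropped.
    """

    labels: tuple
    coordinates: np.ndarray
    eigenvalues: np.ndarray


def kmer_set(seq: str, k: int) -> set[str]:
    """Distinct length-k substrings of ``seq`` (empty set if k > len)."""
    if k < 1:
        raise ValueError("k must be >= 1")
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


def google_distance(s1: str, s2: str, k: int = 3) -> float:
    """Normalized Google distance on k-mer sets; 0 for identical sets, 1 for
    disjoint ones."""
    if len(s1) < k or len(s2) < k:
        raise ValueError(f"sequences must be at least k={k} long")
    a, b = kmer_set(s1, k), kmer_set(s2, k)
    inter = len(a & b)
    return (len(a) + len(b) - 2 * inter) / (len(a) + len(b) - inter)


def lz_complexity(seq: str) -> int:
    """Number of components in the Lempel–Ziv 1976 exhaustive-history parse."""
    n = len(seq)
    if n == 0:
        raise ValueError("empty sequence")
    if n == 1:
        return 1
    # Kaspar–Schuster formulation of the LZ76 production count.
    i, k, l = 0, 1, 1
    k_max = 1
    c = 1
    while True:
        if seq[i + k - 1] == seq[l + k - 1]:
            k += 1
            if l + k > n:
                c += 1
                break
        else:
            k_max = max(k, k_max)
            i += 1
            if i == l:
                c += 1
                l += k_max
                if l + 1 > n:
                    break
                i, k, k_max = 0, 1, 1
            else:
                k = 1
    return c


def lz_distance(s1: str, s2: str) -> float:
    """Otu–Sayood normalized Lempel–Ziv distance; symmetric, non-negative."""
    if not s1 or not s2:
        raise ValueError("empty sequence")
    c1, c2 = lz_complexity(s1), lz_complexity(s2)
    c12, c21 = lz_complexity(s1 + s2), lz_complexity(s2 + s1)
    return max(c12 - c1, c21 - c2) / max(c1, c2)


def blosum62_distance(s1: str, s2: str) -> float:
    """Score-based dissimilarity of two equal-length gap-aligned sequences.

    Over columns where neither sequence is gapped, with Sxy the summed
    BLOSUM62 scores of the column pairs: ``d = 1 - S12 / max(S11, S22)``.
    """
    if len(s1) != len(s2):
        raise ValueError("aligned sequences must have equal length")
    s11 = s22 = s12 = 0.0
    n_cols = 0
    for a, b in zip(s1, s2):
        if a in GAP_CHARS or b in GAP_CHARS:
            continue
        n_cols += 1
        s11 += _BLOSUM62[a, a]
        s22 += _BLOSUM62[b, b]
        s12 += _BLOSUM62[a, b]
    if n_cols == 0:
        raise ValueError("no ungapped column overlap")
    return 1.0 - s12 / max(s11, s22)


_METRICS: dict[str, Callable[..., float]] = {
    "google": google_distance,
    "lz": lambda s1, s2: lz_distance(s1, s2),
    "blosum62": lambda s1, s2: blosum62_distance(s1, s2),
}


def pairwise_distance_matrix(
    seqs: Mapping[str, str], metric: str = "google", **params
) -> DistanceMatrix:
    """Apply a named metric (``google``, ``lz``, ``blosum62``) to every pair."""
    if metric not in _METRICS:
        raise ValueError(f"unknown metric {metric!r}; choose from {sorted(_METRICS)}")
    labels = tuple(seqs)
    if len(labels) < 2:
        raise ValueError("need at least two sequences")
    fn = _METRICS[metric]
    n = len(labels)
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            try:
                d = fn(seqs[labels[i]], seqs[labels[j]], **params)
            except Exception as exc:
                raise ValueError(
                    f"metric {metric!r} failed on pair ({labels[i]}, {labels[j]}): {exc}"
                ) from exc
            values[i, j] = values[j, i] = d
    return DistanceMatrix(labels, values)


def pcoa(dm: DistanceMatrix | np.ndarray, n_axes: int | None = None,
         labels: Sequence[str] | None = None) -> PCoAResult:
    """Classical (Torgerson) principal coordinates analysis.

    Gower-centers ``-0.5 * D**2``, eigendecomposes, and returns coordinates on
    the axes with positive eigenvalues (largest first), truncated to
    ``n_axes`` if given.  All eigenvalues, including negative ones from
    non-Euclidean distances, are reported.
    """
    if isinstance(dm, DistanceMatrix):
        d = dm.values
        labels = dm.labels
    else:
        d = np.asarray(dm, dtype=float)
        if d.ndim != 2 or d.shape[0] != d.shape[1] or not np.allclose(d, d.T):
            raise ValueError("distance matrix must be square and symmetric")
        if labels is None:
            labels = tuple(str(i) for i in range(d.shape[0]))
    n = d.shape[0]
    if n < 2:
        raise ValueError("need at least two points")
    b = -0.5 * d**2
    centerer = np.eye(n) - np.ones((n, n)) / n
    b = centerer @ b @ centerer
    eigvals, eigvecs = np.linalg.eigh((b + b.T) / 2)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    tol = max(abs(eigvals[0]), 1.0) * 1e-12
    positive = eigvals > tol
    coords = eigvecs[:, positive] * np.sqrt(eigvals[positive])
    if n_axes is not None:
        coords = coords[:, :n_axes]
    return PCoAResult(tuple(labels), coords, eigvals)
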