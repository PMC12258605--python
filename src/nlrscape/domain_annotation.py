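"""Domain-hit parsing, competing-annotation resolution, and NLR calling.

Candidate NLRs are annotated by HMM searches against three profile
collections — curated fungal-NLR profiles (``wojciechowski``), an
order-specific set built from Sordariales alignments
(``sordariales_specific``), and Pfam-A (``pfam_a``).  The same protein region
frequently attracts several overlapping predictions; this module resolves
them with two rules:

* different sources: the higher-priority source wins outright, with priority
  wojciechowski > sordariales_specific > pfam_a;
* same source: the best (lowest-E-value) prediction is retained only when its
  E-value is strictly lower than the *square* of every competitor's E-value;
  otherwise the region is called undetermined when the competition concerns
  NB-class profiles, and all predictions are kept (status ``multiple``)
  otherwise.

Profiles map to canonical categories (with the historical merges sesA →
HeLo-like and NAD1 → Goodbye-like, and all amyloid-motif profiles pooled as
"amyloid").  A candidate NLR is a gene longer than 1 kb carrying at least one
canonical NB call and a canonical C-terminal repeat call downstream of it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

SOURCE_PRIORITY = {"wojciechowski": 0, "sordariales_specific": 1, "pfam_a": 2}

#: Floor applied to E-values of exactly zero before squaring.
EVALUE_FLOOR = 1e-300

HIT_COLUMNS = ["gene_id", "profile", "source", "aa_start", "aa_end", "evalue", "score"]
CALL_COLUMNS = HIT_COLUMNS + ["category", "category_class", "status"]

# Canonical category classes.
NTERM_CANONICAL = ("HeLo-like", "sesB-like", "Goodbye-like", "HET-like",
                   "PNP_UDP_1", "RelA_SpoT", "Patatin", "amyloid")
CTERM_CANONICAL = ("Ankyrin", "TPR", "WD40", "HEAT")
NB_CATEGORIES = ("NACHT", "NB-ARC")


@dataclass(frozen=True)
class DomainHit:
    gene_id: str
    profile: str
    source: str
    aa_start: int
    aa_end: int
    evalue: float
    score: float

    def __post_init__(self):
        if self.aa_start > self.aa_end:
            raise ValueError(f"{self.gene_id}/{self.profile}: aa_start > aa_end")
        if self.evalue <= 0:
            object.__setattr__(self, "evalue", EVALUE_FLOOR)


@dataclass
class CategoryMap:
    """Profile → (category, category class) lookup.

    ``category_class`` is one of ``nterm``, ``nb``, ``cterm``, ``amyloid``;
    profiles absent from the map are non-canonical and keep their own name as
    category.  Amyloid-class categories count as canonical N-terminal domains
    for architecture purposes.
    """

    profile_to_category: dict = field(default_factory=dict)
    category_to_class: dict = field(default_factory=dict)

    def category(self, profile: str) -> str:
        return self.profile_to_category.get(profile, profile)

    def category_class(self, profile: str) -> str:
        cat = self.category(profile)
        return self.category_to_class.get(cat, "noncanonical")

    @classmethod
    def from_table(cls, table: pd.DataFrame) -> "CategoryMap":
        """Build from a table with columns profile, category, category_class."""
        m = cls()
        for row in table.itertuples(index=False):
            m.profile_to_category[row.profile] = row.category
            m.category_to_class[row.category] = row.category_class
        return m

    def to_table(self) -> pd.DataFrame:
        rows = [
            (p, c, self.category_to_class.get(c, "noncanonical"))
            for p, c in sorted(self.profile_to_category.items())
        ]
        return pd.DataFrame(rows, columns=["profile", "category", "category_class"])


def default_category_map() -> CategoryMap:
    """The built-in profile → category map with the canonical merges."""
    m = CategoryMap()
    nterm = {
        "HeLo": "HeLo-like", "HeLo_like": "HeLo-like", "sesA": "HeLo-like",
        "sesB": "sesB-like", "SesB": "sesB-like",
        "Goodbye": "Goodbye-like", "NAD1": "Goodbye-like",
        "HET": "HET-like", "Het": "HET-like",
        "PNP_UDP_1": "PNP_UDP_1", "RelA_SpoT": "RelA_SpoT", "Patatin": "Patatin",
    }
    amyloid = {"HET-s_218-289": "amyloid", "PP_motif": "amyloid", "sigma_motif": "amyloid"}
    nb = {"NACHT": "NACHT", "T-NACHT": "NACHT", "N-NACHT": "NACHT",
          "NB-ARC": "NB-ARC"}
    cterm = {"Ank": "Ankyrin", "Ank_2": "Ankyrin", "Ank_4": "Ankyrin",
             "TPR": "TPR", "TPR_1": "TPR", "TPR_2": "TPR",
             "WD40": "WD40", "HEAT": "HEAT", "HEAT_2": "HEAT"}
    for d, klass in ((nterm, "nterm"), (amyloid, "amyloid"), (nb, "nb"), (cterm, "cterm")):
        for profile, cat in d.items():
            m.profile_to_category[profile] = cat
            m.category_to_class[cat] = klass
    return m


def categorize_domain(profile: str, category_map: CategoryMap | None = None) -> str:
    """Canonical category of a profile; unknown profiles are non-canonical
    and labelled with their own name."""
    cm = category_map if category_map is not None else default_category_map()
    return cm.category(profile)


def load_domtblout(path, source: str = "pfam_a") -> pd.DataFrame:
    """Parse an HMMER3 per-domain table (``--domtblout`` dialect).

    One row per domain, envelope coordinates, independent (i-)E-value and
    per-domain bit score.  ``#`` lines are comments.  The target name is the
    gene/protein id and the query name the profile.  ``source`` labels which
    profile collection the search used.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 22:
                raise ValueError(f"{path}: malformed domtblout row at line {lineno}")
            try:
                rows.append(
                    (
                        parts[0],            # target (gene) name
                        parts[3],            # query (profile) name
                        source,
                        int(parts[19]),      # env from
                        int(parts[20]),      # env to
                        float(parts[12]),    # i-Evalue
                        float(parts[13]),    # domain bit score
                    )
                )
            except ValueError as exc:
                raise ValueError(
                    f"{path}: malformed domtblout row at line {lineno}: {exc}"
                ) from None
    return pd.DataFrame(rows, columns=HIT_COLUMNS)


def _overlap_fraction(a: DomainHit, b: DomainHit) -> float:
    ov = min(a.aa_end, b.aa_end) - max(a.aa_start, b.aa_start) + 1
    if ov <= 0:
        return 0.0
    shorter = min(a.aa_end - a.aa_start, b.aa_end - b.aa_start) + 1
    return ov / shorter


def _hits_from_table(hits: pd.DataFrame | Iterable[DomainHit]) -> list[DomainHit]:
    if isinstance(hits, pd.DataFrame):
        return [DomainHit(**{k: row[k] for k in HIT_COLUMNS}) for _, row in hits.iterrows()]
    return list(hits)


def _components(hits: Sequence[DomainHit], overlap_fraction: float) -> list[list[DomainHit]]:
    """Connected components of the hit-overlap graph (transitive closure of
    pairwise overlap >= overlap_fraction of the shorter interval)."""
    n = len(hits)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if _overlap_fraction(hits[i], hits[j]) >= overlap_fraction:
                parent[find(i)] = find(j)
    groups: dict[int, list[DomainHit]] = {}
    for i, h in enumerate(hits):
        groups.setdefault(find(i), []).append(h)
    # deterministic order: by leftmost member coordinate, then profile name
    return sorted(groups.values(), key=lambda g: (min(h.aa_start for h in g),
                                                  min(h.profile for h in g)))


def _resolve_component(
    comp: list[DomainHit], cm: CategoryMap
) -> list[tuple[DomainHit, str]]:
    """Resolve one competition group; returns (hit, status) pairs."""
    if len(comp) == 1:
        return [(comp[0], "resolved")]
    best_priority = min(SOURCE_PRIORITY[h.source] for h in comp)
    top = [h for h in comp if SOURCE_PRIORITY[h.source] == best_priority]
    if len(top) == 1:
        return [(top[0], "resolved")]
    # same-source competition: squared-E-value rule, best vs every competitor
    top = sorted(top, key=lambda h: (h.evalue, h.profile, h.aa_start))
    best = top[0]
    if all(best.evalue < max(h.evalue, EVALUE_FLOOR) ** 2 for h in top[1:]):
        return [(best, "resolved")]
    if any(cm.category_class(h.profile) == "nb" for h in comp):
        return [(h, "undetermined") for h in top]
    return [(h, "multiple") for h in top]


def resolve_competing_hits(
    hits: pd.DataFrame | Iterable[DomainHit],
    overlap_fraction: float = 0.5,
    category_map: CategoryMap | None = None,
) -> pd.DataFrame:
    """Resolve overlapping domain predictions per gene.

    Hits overlapping by at least ``overlap_fraction`` of the shorter interval
    compete (transitively).  Cross-source competitions are decided by source
    priority; same-source ones by the squared-E-value rule.  Returns a call
    table with columns ``gene_id, profile, source, aa_start, aa_end, evalue,
    score, category, category_class, status``.
    """
    if not 0 < overlap_fraction <= 1:
        raise ValueError("overlap_fraction must be in (0, 1]")
    cm = category_map if category_map is not None else default_category_map()
    all_hits = _hits_from_table(hits)
    rows = []
    by_gene: dict[str, list[DomainHit]] = {}
    for h in all_hits:
        by_gene.setdefault(h.gene_id, []).append(h)
    for gene_id in sorted(by_gene):
        gene_hits = sorted(by_gene[gene_id], key=lambda h: (h.aa_start, h.aa_end, h.profile))
        for comp in _components(gene_hits, overlap_fraction):
            for h, status in _resolve_component(comp, cm):
                rows.append(
                    (h.gene_id, h.profile, h.source, h.aa_start, h.aa_end,
                     h.evalue, h.score, cm.category(h.profile),
                     cm.category_class(h.profile), status)
                )
    return pd.DataFrame(rows, columns=CALL_COLUMNS)


def call_nlr_candidates(
    calls: pd.DataFrame, gene_lengths: Mapping[str, int], min_gene_bp: int = 1000
) -> set[str]:
    """Candidate NLRs: >= 1 NB call, a canonical C-terminal repeat call
    downstream of it, and gene length strictly greater than 1 kb.

    An NB competition left ``undetermined`` still attests an NB domain (its
    type, not its presence, is what is undetermined), so it counts here.
    """
    candidates = set()
    for gene_id, sub in calls.groupby("gene_id"):
        if gene_id not in gene_lengths:
            raise KeyError(f"no gene length for {gene_id}")
        if gene_lengths[gene_id] <= min_gene_bp:
            continue
        nb = sub[sub["category_class"] == "nb"]
        ct = sub[(sub["category_class"] == "cterm") & (sub["status"] != "undetermined")]
        if nb.empty or ct.empty:
            continue
        first_nb_end = nb["aa_end"].min()
        if (ct["aa_start"] > first_nb_end).any():
            candidates.add(gene_id)
    return candidates


_N_TRUNCATION_AA = 20   # shorter N-terminal region than this, with no call: truncated
_C_TRUNCATION_AA = 50   # same for the C-terminal region


def classify_architecture(calls: pd.DataFrame, protein_length: int) -> str:
    """Architecture class of one gene's resolved calls.

    Calls are assigned to the N- or C-terminal side by their midpoint
    relative to the NB-region midpoint.  Each side is then canonical (exactly
    one canonical category), ``mixed`` (two or more distinct canonical
    categories), ``non-canonical`` (only non-canonical calls),
    ``missing`` (no call and the flanking region is shorter than 20 aa
    N-terminally / 50 aa C-terminally), or ``undetermined`` (no call, room for
    one).  Overall: mixed on either side wins, then tripartite (both sides
    canonical), then the missing/non-canonical/undetermined combinations.
    """
    ok = calls[calls["status"] != "undetermined"]
    nb = ok[ok["category_class"] == "nb"]
    if nb.empty:
        return "undetermined"
    nb_start, nb_end = int(nb["aa_start"].min()), int(nb["aa_end"].max())
    nb_mid = (nb_start + nb_end) / 2

    side: dict[str, list] = {"N": [], "C": []}
    for row in ok.itertuples(index=False):
        if row.category_class == "nb":
            continue
        mid = (row.aa_start + row.aa_end) / 2
        side["N" if mid < nb_mid else "C"].append(row)

    def side_status(which: str) -> str:
        rows = side[which]
        canon_classes = {"nterm", "amyloid"} if which == "N" else {"cterm"}
        canonical = {r.category for r in rows if r.category_class in canon_classes}
        if len(canonical) >= 2:
            return "mixed"
        if len(canonical) == 1:
            return "canonical"
        if rows:  # only non-canonical calls on this side
            return "non-canonical"
        room = (nb_start - 1) if which == "N" else (protein_length - nb_end)
        limit = _N_TRUNCATION_AA if which == "N" else _C_TRUNCATION_AA
        return "missing" if room < limit else "undetermined"

    n_status, c_status = side_status("N"), side_status("C")
    if "mixed" in (n_status, c_status):
        return "mixed"
    if n_status == "canonical" and c_status == "canonical":
        return "tripartite"
    if n_status == "missing" and c_status == "missing":
        return "missing-both"
    if n_status == "missing":
        return "missing-N"
    if c_status == "missing":
        return "missing-C"
    if "non-canonical" in (n_status, c_status):
        return "non-canonical"
    return "undetermined"


def merge_overlapping_intervals(intervals: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    """Minimal sorted set of disjoint intervals covering the union.

    Intervals are closed over integer coordinates, so ones that share an
    endpoint or abut (end + 1 == next start) merge into one covered run.
    """
    ivs = sorted(intervals)
    if not ivs:
        return []
    merged = [list(ivs[0])]
    for start, end in ivs[1:]:
        if start <= merged[-1][1] + 1:
            merged[-1][1] = max(merged[-1][1], end)
        else:
            merged.append([start, end])
    return [tuple(iv) for iv in merged]


def filter_alignment_hits(
    hits: pd.DataFrame,
    nb_intervals: Iterable[tuple[int, int]],
    min_score: float = 200.0,
) -> pd.DataFrame:
    """Post-filter protein-to-genome alignment hits.

    A hit survives iff its score is at least ``min_score``, it overlaps some
    NB-domain interval by at least 1 bp, and it carries neither a stop codon
    nor a frameshift.  Expects columns ``start, end, score, has_stop,
    has_frameshift``.
    """
    nb = list(nb_intervals)

    def overlaps_nb(start, end):
        return any(start <= e and end >= s for s, e in nb)

    keep = [
        row.score >= min_score
        and not row.has_stop
        and not row.has_frameshift
        and overlaps_nb(row.start, row.end)
        for row in hits.itertuples(index=False)
    ]
    return hits[pd.Series(keep, index=hits.index)].reset_index(drop=True)
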