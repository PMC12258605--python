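"""Typing of NLR nucleotide-binding (NB) domains.

Fungal NLRs carry one of two lineages of NB domain, NACHT or NB-ARC, and the
NACHT lineage further splits into a rare NAIP-like form (N-NACHT) and the
common TLP1-like form (T-NACHT).  The two lineages are distinguished by the
Walker B motif of the P-loop NTPase core: in NACHT domains the first aspartate
is followed by a small residue (G/A/S) with a second acidic residue three
positions downstream, giving the consensus ``hhhhD[GAS]hDE``; in NB-ARC
domains the first aspartate is directly followed by another acidic residue.
The NACHT subtypes are told apart by the HETHS (HElical THird domain of STAND
proteins, also called winged-helix or ARC2) region C-terminal of the core
domain: the NAIP-like form carries the consensus ``FhHxxhQE[YF]hxA`` there.

This module implements a small degenerate-motif engine (``h`` = hydrophobic,
``x`` = any residue, ``[...]`` = residue class, letters = literals), the
Walker B classifier, the NACHT subtype classifier, and the split of an NB
sequence into the two fragments used for alignment-free ordination.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterator, Optional

__all__ = [
    "HYDROPHOBIC",
    "DegenerateMotif",
    "MotifMatch",
    "NBTypeCall",
    "WALKER_A",
    "WALKER_B_NACHT",
    "WALKER_B_NBARC",
    "HETHS_NAIP",
    "match_motif",
    "classify_walker_b",
    "classify_nacht_subtype",
    "type_nb_domain",
    "split_nb_fragments",
]

#: Residues matched by the ``h`` (hydrophobic) wildcard, Leipe-style convention.
HYDROPHOBIC = frozenset("ACFILMVWY")

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

_MOTIF_TOKEN = re.compile(r"\[([A-Z]+)\]|([A-Zhx])")


@dataclass(frozen=True)
class DegenerateMotif:
    """A positional motif over the amino-acid alphabet.

    Each position is a frozenset of residues it accepts.  ``h`` expands to the
    hydrophobic set, ``x`` to any residue (including the ambiguity code X),
    ``[GAS]`` to the listed residues, and a capital letter to itself.
    """

    pattern: str
    hydrophobic: frozenset = HYDROPHOBIC
    positions: tuple = field(init=False)

    def __post_init__(self) -> None:
        positions = []
        pos = 0
        for m in _MOTIF_TOKEN.finditer(self.pattern):
            if m.start() != pos:
                raise ValueError(f"cannot parse motif {self.pattern!r} at offset {pos}")
            pos = m.end()
            cls, lit = m.group(1), m.group(2)
            if cls is not None:
                if not cls:
                    raise ValueError("empty residue class")
                positions.append(frozenset(cls))
            elif lit == "h":
                positions.append(frozenset(self.hydrophobic))
            elif lit == "x":
                positions.append(None)  # any residue
            else:
                positions.append(frozenset(lit))
        if pos != len(self.pattern):
            raise ValueError(f"cannot parse motif {self.pattern!r} at offset {pos}")
        if not positions:
            raise ValueError("empty motif")
        object.__setattr__(self, "positions", tuple(positions))

    def __len__(self) -> int:
        return len(self.positions)

    def matches_at(self, seq: str, i: int) -> bool:
        """True if the motif matches ``seq`` at 0-based offset ``i``."""
        if i < 0 or i + len(self.positions) > len(seq):
            return False
        for allowed, residue in zip(self.positions, seq[i : i + len(self.positions)]):
            if allowed is None:
                continue  # 'x' — any residue, X included
            if residue not in allowed:
                return False
        return True

    def expand(self, limit: int = 10**6) -> Iterator[str]:
        """Yield every literal string the motif accepts (``x`` over the 20 aa).

        Intended for small motifs (brute-force oracles); raises if the
        expansion would exceed ``limit`` strings.
        """
        size = 1
        sets = []
        for allowed in self.positions:
            residues = AMINO_ACIDS if allowed is None else "".join(sorted(allowed))
            sets.append(residues)
            size *= len(residues)
            if size > limit:
                raise ValueError(f"expansion exceeds {limit} strings")

        def rec(prefix: str, rest: list) -> Iterator[str]:
            if not rest:
                yield prefix
                return
            for r in rest[0]:
                yield from rec(prefix + r, rest[1:])

        yield from rec("", sets)


@dataclass(frozen=True)
class MotifMatch:
    """One placement of a motif on a protein sequence (1-based)."""

    aa_start: int
    matched_substring: str
    motif_id: str

    @property
    def aa_end(self) -> int:
        """1-based inclusive end position."""
        return self.aa_start + len(self.matched_substring) - 1


#: Classical P-loop (Walker A) consensus.
WALKER_A = DegenerateMotif("GxxxxGK[ST]")
#: NACHT-diagnostic Walker B: D-[GAS]-h then acidic pair three positions on.
WALKER_B_NACHT = DegenerateMotif("hhhhD[GAS]hDE")
#: NB-ARC-diagnostic Walker B: first aspartate directly followed by an acidic
#: residue.
WALKER_B_NBARC = DegenerateMotif("hhhhD[DE]")
#: NAIP-like HETHS consensus; its presence downstream of the Walker B defines
#: the N-NACHT subtype.
HETHS_NAIP = DegenerateMotif("FhHxxhQE[YF]hxA")


@dataclass(frozen=True)
class NBTypeCall:
    nb_type: str  # "T-NACHT" | "N-NACHT" | "NB-ARC" | "undetermined"
    walkerB_match: Optional[MotifMatch] = None
    heths_match: Optional[MotifMatch] = None


def match_motif(seq: str, motif: DegenerateMotif, motif_id: str | None = None) -> list[MotifMatch]:
    """All placements of ``motif`` on ``seq``, left to right, 1-based starts."""
    if len(motif) == 0:
        raise ValueError("empty motif")
    mid = motif_id if motif_id is not None else motif.pattern
    out = []
    for i in range(len(seq) - len(motif) + 1):
        if motif.matches_at(seq, i):
            out.append(MotifMatch(i + 1, seq[i : i + len(motif)], mid))
    return out


def classify_walker_b(seq: str) -> tuple[str, Optional[MotifMatch]]:
    """Classify the Walker B motif of ``seq`` as NACHT, NB-ARC, or neither.

    The NACHT consensus takes precedence: a sequence matching
    ``hhhhD[GAS]hDE`` anywhere is NACHT even if an NB-ARC-style Walker B also
    occurs.  The leftmost match of the winning motif is reported.
    """
    nacht = match_motif(seq, WALKER_B_NACHT, "walker_b_nacht")
    if nacht:
        return "NACHT", nacht[0]
    nbarc = match_motif(seq, WALKER_B_NBARC, "walker_b_nbarc")
    if nbarc:
        return "NB-ARC", nbarc[0]
    return "neither", None


def classify_nacht_subtype(seq: str, walkerB: MotifMatch) -> tuple[str, Optional[MotifMatch]]:
    """Split a NACHT sequence into N-NACHT vs T-NACHT by the HETHS region.

    The NAIP-like HETHS consensus is searched strictly downstream of the
    Walker B match (the HETHS lies C-terminal of the core P-loop domain); a
    hit means N-NACHT, otherwise T-NACHT.
    """
    tail_offset = walkerB.aa_end  # 0-based index of first residue after Walker B
    tail = seq[tail_offset:]
    hits = match_motif(tail, HETHS_NAIP, "heths_naip")
    if hits:
        h = hits[0]
        return "N-NACHT", MotifMatch(h.aa_start + tail_offset, h.matched_substring, h.motif_id)
    return "T-NACHT", None


def type_nb_domain(seq: str) -> NBTypeCall:
    """Full three-way NB typing: T-NACHT / N-NACHT / NB-ARC / undetermined."""
    kind, wb = classify_walker_b(seq)
    if kind == "neither":
        return NBTypeCall("undetermined")
    if kind == "NB-ARC":
        return NBTypeCall("NB-ARC", walkerB_match=wb)
    subtype, heths = classify_nacht_subtype(seq, wb)
    return NBTypeCall(subtype, walkerB_match=wb, heths_match=heths)


def split_nb_fragments(seq: str, walkerB_start: int) -> tuple[str, str]:
    """Split an NB sequence at the start of the Walker B motif.

    Fragment 1 runs from the N-terminus up to (not including) the Walker B
    start; fragment 2 from the Walker B start to the C-terminus.  Their
    concatenation reconstructs the input.
    """
    if not 1 < walkerB_start <= len(seq):
        raise ValueError(
            f"walkerB_start={walkerB_start} out of range for sequence of length {len(seq)}"
        )
    return seq[: walkerB_start - 1], seq[walkerB_start - 1 :]
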