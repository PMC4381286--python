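"""Gapped zinc-binding-motif (ZB-motif) patterns and sequence scanning.

ZB-motifs are short cysteine/tyrosine/histidine patterns whose anchored
residues can coordinate a Zn2+ ion, written in the field's compact
notation, e.g. ``CxCx20-21Yx3C``: a Cys, one arbitrary residue, a Cys,
20-21 arbitrary residues, a Tyr, three arbitrary residues, a Cys.  This
module parses that notation into executable patterns, scans protein
sequences for every realisation of a pattern (overlaps and alternative
gap lengths included), and classifies a sequence by the highest-priority
catalog pattern it contains.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass, field

__all__ = [
    "AMINO_ACIDS",
    "MotifPattern",
    "MotifHit",
    "DisruptedHit",
    "parse_pattern",
    "scan_sequence",
    "scan_disrupted",
    "classify_motif",
    "catalog_for",
    "CATALOGS",
    "TAXA",
]

AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWY")

TAXA = ("bacteria-GluRS", "bacteria-GluQRS", "archaea-GluRS", "eukarya-GluRS")


class MotifParseError(ValueError):
    """Raised when a motif notation string cannot be parsed."""


@dataclass(frozen=True)
class MotifPattern:
    """A parsed gapped motif.

    ``elements`` alternates residue sets and (gap_min, gap_max) bounds,
    stored as a tuple of residue sets plus a parallel tuple of gaps:
    ``residue_sets[i]`` is followed by ``gaps[i]`` arbitrary residues,
    for i < len(residue_sets) - 1.
    """

    name: str
    taxon: str
    residue_sets: tuple[frozenset, ...]
    gaps: tuple[tuple[int, int], ...]
    source_string: str = ""

    def __post_init__(self):
        if not self.residue_sets:
            raise MotifParseError("pattern has no anchored residues")
        if len(self.gaps) != len(self.residue_sets) - 1:
            raise MotifParseError("gap/anchor count mismatch")
        for rs in self.residue_sets:
            bad = set(rs) - AMINO_ACIDS
            if bad:
                raise MotifParseError(f"non-amino-acid letters in residue set: {sorted(bad)}")
        for lo, hi in self.gaps:
            if lo < 0 or hi < lo:
                raise MotifParseError(f"invalid gap bounds ({lo}, {hi})")

    @property
    def n_anchors(self) -> int:
        return len(self.residue_sets)

    @property
    def min_span(self) -> int:
        return self.n_anchors + sum(lo for lo, _ in self.gaps)

    def notation(self) -> str:
        """Re-serialise to the compact notation (canonical form)."""
        parts = []
        for i, rs in enumerate(self.residue_sets):
            parts.append(next(iter(rs)) if len(rs) == 1 else "[" + "".join(sorted(rs)) + "]")
            if i < len(self.gaps):
                lo, hi = self.gaps[i]
                if lo == hi == 0:
                    continue
                if lo == hi == 1:
                    parts.append("x")
                elif lo == hi:
                    parts.append(f"x{lo}")
                else:
                    parts.append(f"x{lo}-{hi}")
        return "".join(parts)


@dataclass(frozen=True)
class MotifHit:
    """One realised match: anchored positions plus the gap lengths used.

    Coordinates are 0-based; ``end`` is exclusive (one past the last
    anchored residue).
    """

    pattern_name: str
    start: int
    end: int
    anchored_positions: tuple[int, ...]
    matched_gaps: tuple[int, ...]


@dataclass(frozen=True)
class DisruptedHit:
    """A near-miss: a gap-consistent placement where only some anchors match."""

    pattern_name: str
    start: int
    anchored_positions: tuple[int, ...]
    matched_mask: tuple[bool, ...]
    n_matched: int


# Token grammar: residue letter, bracketed residue set, or gap token
# "x" / "x<n>" / "x<a>-<b>" (underscores, braces and en-dashes tolerated).
_TOKEN = re.compile(
    r"""
    (?P<set>\[[A-Za-z]+\])
  | (?P<gap>[xX](?:_?\{?(?P<lo>\d+)(?:\s*[-–]\s*(?P<hi>\d+))?\}?_?)?)
  | (?P<res>[A-WYZa-wyz])
  | (?P<bad>.)
    """,
    re.VERBOSE,
)


def parse_pattern(notation: str, name: str = "", taxon: str = "") -> MotifPattern:
    """Parse compact motif notation into a :class:`MotifPattern`.

    ``x`` alone denotes exactly one arbitrary residue, ``x20`` exactly 20,
    ``x20-21`` any count in [20, 21].  Adjacent gap tokens accumulate.

    Raises
    ------
    MotifParseError
        On empty input, a dangling gap (pattern not ending in a residue),
        letters outside the 20 standard amino acids, or reversed bounds.
    """
    if not notation or not notation.strip():
        raise MotifParseError("empty motif notation")
    residue_sets: list[frozenset] = []
    gaps: list[tuple[int, int]] = []
    pending = (0, 0)  # gap accumulated since the previous anchor

    def push_anchor(rs: frozenset):
        nonlocal pending
        if residue_sets:
            gaps.append(pending)
        residue_sets.append(rs)
        pending = (0, 0)

    for m in _TOKEN.finditer(notation.strip()):
        if m.lastgroup == "bad" or m.group("bad"):
            raise MotifParseError(f"unexpected character {m.group(0)!r} in {notation!r}")
        if m.group("set"):
            letters = frozenset(m.group("set")[1:-1].upper())
            if not letters <= AMINO_ACIDS:
                raise MotifParseError(f"non-amino-acid letters in {m.group(0)!r}")
            push_anchor(letters)
        elif m.group("gap") is not None and m.group(0).lower().startswith("x"):
            if not residue_sets:
                raise MotifParseError("pattern may not start with a gap")
            lo_s, hi_s = m.group("lo"), m.group("hi")
            if lo_s is None:
                lo = hi = 1
            else:
                lo = int(lo_s)
                hi = int(hi_s) if hi_s is not None else lo
            if hi < lo:
                raise MotifParseError(f"gap bounds reversed in token {m.group(0)!r}")
            pending = (pending[0] + lo, pending[1] + hi)
        else:
            letter = m.group("res").upper()
            if letter not in AMINO_ACIDS:
                raise MotifParseError(f"{letter!r} is not a standard amino acid")
            push_anchor(frozenset(letter))
    if not residue_sets:
        raise MotifParseError(f"no anchored residues in {notation!r}")
    if pending != (0, 0):
        raise MotifParseError(f"dangling gap at end of {notation!r}")
    return MotifPattern(
        name=name or notation,
        taxon=taxon,
        residue_sets=tuple(residue_sets),
        gaps=tuple(gaps),
        source_string=notation,
    )


# Catalogs follow the published per-taxon groupings; order encodes priority
# (canonical before modified motif).
_CATALOG_DEFS = {
    "bacteria-GluRS": [("bact-I", "CxCx20-21Yx3C"), ("bact-II", "CxCx20Yx3H")],
    "bacteria-GluQRS": [("eqrs-I", "CxCx11-28Yx3C")],
    "archaea-GluRS": [("arch-I", "CxCx14CxC"), ("arch-II", "CxCx14CxH")],
    "eukarya-GluRS": [("euk-I", "CxCx20Yx3C"), ("euk-II", "CxCx20Cx3C")],
}

CATALOGS: dict[str, tuple[MotifPattern, ...]] = {
    taxon: tuple(parse_pattern(s, name=n, taxon=taxon) for n, s in defs)
    for taxon, defs in _CATALOG_DEFS.items()
}


def catalog_for(taxon: str) -> tuple[MotifPattern, ...]:
    """Return the built-in motif catalog for a taxon, in priority order."""
    try:
        return CATALOGS[taxon]
    except KeyError:
        raise ValueError(f"unknown taxon {taxon!r}; expected one of {TAXA}") from None


def _validate_sequence(seq: str) -> str:
    seq = seq.upper()
    bad = set(seq) - AMINO_ACIDS - {"X"}
    if bad:
        raise ValueError(f"non-amino-acid characters in sequence: {sorted(bad)}")
    return seq


def scan_sequence(
    seq: str,
    patterns,
    window: tuple[int, int] | None = None,
) -> list[MotifHit]:
    """Find every realised match of every pattern in ``seq``.

    All overlapping matches and all alternative gap realisations are
    reported.  Ordering: leftmost start first, then pattern catalog order,
    then shorter realised gaps first.  The unknown-residue letter ``X``
    never satisfies an anchor but does count toward gap lengths.  If
    ``window`` (0-based half-open) is given, only matches whose anchored
    residues all lie inside it are reported.
    """
    if isinstance(patterns, MotifPattern):
        patterns = [patterns]
    seq = _validate_sequence(seq)
    n = len(seq)
    if window is None:
        lo_w, hi_w = 0, n
    else:
        lo_w, hi_w = window
        if not (0 <= lo_w <= hi_w <= n):
            raise ValueError(f"window {window} outside sequence of length {n}")
    hits: list[MotifHit] = []
    for p_idx, pat in enumerate(patterns):
        for start in range(lo_w, hi_w):
            if start + pat.min_span > hi_w:
                break
            for gap_combo in itertools.product(
                *[range(lo, hi + 1) for lo, hi in pat.gaps]
            ):
                pos = start
                anchored = []
                ok = True
                for k, rs in enumerate(pat.residue_sets):
                    if pos >= hi_w or seq[pos] not in rs:
                        ok = False
                        break
                    anchored.append(pos)
                    if k < len(gap_combo):
                        pos += 1 + gap_combo[k]
                if ok:
                    hits.append(
                        MotifHit(
                            pattern_name=pat.name,
                            start=anchored[0],
                            end=anchored[-1] + 1,
                            anchored_positions=tuple(anchored),
                            matched_gaps=tuple(gap_combo),
                        )
                    )
        # order within a pattern is already leftmost-then-shortest-gap
    hits.sort(key=lambda h: (h.start, _pattern_rank(h.pattern_name, patterns), h.matched_gaps))
    return hits


def _pattern_rank(name: str, patterns) -> int:
    for i, p in enumerate(patterns):
        if p.name == name:
            return i
    return len(patterns)


def scan_disrupted(
    seq: str,
    pattern: MotifPattern,
    min_anchor_matches: int = 2,
    window: tuple[int, int] | None = None,
) -> list[DisruptedHit]:
    """Report near-miss placements of ``pattern``.

    A disrupted hit is a gap-consistent placement where at least
    ``min_anchor_matches`` anchored positions (but not all of them) carry
    a residue from their set — e.g. the naturally occurring disrupted
    motif C-x-M-x20-Y-x3-W scanned with the canonical pattern.  Used
    descriptively only; never for group assignment.
    """
    seq = _validate_sequence(seq)
    n = len(seq)
    if window is None:
        lo_w, hi_w = 0, n
    else:
        lo_w, hi_w = window
    out: list[DisruptedHit] = []
    seen = set()
    for start in range(lo_w, hi_w):
        if start + pattern.min_span > hi_w:
            break
        for gap_combo in itertools.product(
            *[range(lo, hi + 1) for lo, hi in pattern.gaps]
        ):
            pos = start
            anchored, mask = [], []
            in_bounds = True
            for k, rs in enumerate(pattern.residue_sets):
                if pos >= hi_w:
                    in_bounds = False
                    break
                anchored.append(pos)
                mask.append(seq[pos] in rs)
                if k < len(gap_combo):
                    pos += 1 + gap_combo[k]
            if not in_bounds:
                continue
            n_matched = sum(mask)
            if min_anchor_matches <= n_matched < pattern.n_anchors:
                key = tuple(anchored)
                if key in seen:
                    continue
                seen.add(key)
                out.append(
                    DisruptedHit(
                        pattern_name=pattern.name,
                        start=anchored[0],
                        anchored_positions=tuple(anchored),
                        matched_mask=tuple(mask),
                        n_matched=n_matched,
                    )
                )
    return out


def classify_motif(hits: list[MotifHit], taxon: str) -> str:
    """Label a sequence by its highest-priority matching catalog pattern.

    Priority is catalog order (canonical motif before modified).  Returns
    ``"none"`` when no catalog pattern matched.
    """
    catalog = catalog_for(taxon)
    present = {h.pattern_name for h in hits}
    for pat in catalog:
        if pat.name in present:
            return pat.name
    return "none"
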