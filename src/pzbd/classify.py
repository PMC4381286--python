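"""pZBD extraction from anchored alignments and five-group classification.

The putative zinc-binding domain (pZBD) of glutamyl-tRNA synthetase is
the residue stretch between two conserved beta-strands, E3 and E4, of
the N-terminal catalytic domain.  Given a multiple sequence alignment
and the two anchor columns (last column of E3, first column of E4),
each sequence's pZBD window and length are measured in ungapped
coordinates, the zinc-binding-motif scanner is run inside that window,
and the sequence is filed into one of five groups:

I   canonical ZB-motif            IV  motif-free, short (31-36 aa)
II  modified ZB-motif             V   pZBD-deleted (length <= 17)
III motif-free, long (>= 37 aa)

Motif-free lengths 18-30 fall in a gap between the observed populations
and are flagged ``unassigned`` rather than silently filed.
"""

from __future__ import annotations

from dataclasses import dataclass

from . import motifs

__all__ = [
    "AnchorSpec",
    "PZBDAnnotation",
    "extract_pzbd",
    "assign_group",
    "annotate",
    "length_histogram",
    "GROUPS",
]

GROUPS = ("I", "II", "III", "IV", "V", "unassigned")

#: motif scanning for grouping extends this many residues past each side
#: of the pZBD window, so a terminal anchored residue on a strand edge
#: still counts.
SCAN_MARGIN = 3


@dataclass(frozen=True)
class AnchorSpec:
    """Alignment columns anchoring the pZBD: last column of strand E3 and
    first column of strand E4 (both 0-based)."""

    e3_col: int
    e4_col: int

    def __post_init__(self):
        if not (0 <= self.e3_col < self.e4_col):
            raise ValueError(f"require 0 <= e3_col < e4_col, got {self.e3_col}, {self.e4_col}")


@dataclass
class PZBDAnnotation:
    seq_id: str
    pzbd_start: int  # ungapped sequence coordinate, half-open window
    pzbd_end: int
    length: int
    motif_label: str = "none"
    group: str = "unassigned"


_GAP_CHARS = set("-.")


def _check_alignment(records, anchors: AnchorSpec):
    widths = {len(r.seq) for r in records}
    if len(widths) > 1:
        raise ValueError(f"ragged alignment: widths {sorted(widths)}")
    width = widths.pop() if widths else 0
    if records and anchors.e4_col >= width:
        raise ValueError(f"anchor column {anchors.e4_col} outside alignment width {width}")
    return width


def extract_pzbd(records, anchors: AnchorSpec) -> list[PZBDAnnotation]:
    """Measure each sequence's pZBD window between the anchor columns.

    The window is *strictly* between ``e3_col`` and ``e4_col`` (the anchor
    strands themselves never count toward the pZBD), converted to ungapped
    sequence coordinates; ``length`` counts non-gap characters in that
    column range.  A sequence fully gapped between the anchors has length
    0 (a deleted pZBD), which is valid.

    ``records`` is any iterable of Biopython ``SeqRecord``-like objects
    (``.id`` and ``.seq``) of equal aligned width.
    """
    records = list(records)
    _check_alignment(records, anchors)
    out = []
    for rec in records:
        s = str(rec.seq).upper()
        start = sum(1 for c in s[: anchors.e3_col + 1] if c not in _GAP_CHARS)
        length = sum(
            1 for c in s[anchors.e3_col + 1 : anchors.e4_col] if c not in _GAP_CHARS
        )
        out.append(
            PZBDAnnotation(
                seq_id=rec.id,
                pzbd_start=start,
                pzbd_end=start + length,
                length=length,
            )
        )
    return out


def assign_group(length: int, motif_label: str, taxon: str = "bacteria-GluRS") -> str:
    """File a sequence into groups I-V from its pZBD length and motif label.

    Group I/II when the taxon's first/second catalog pattern matched inside
    the pZBD; otherwise by length: V (<= 17, pZBD-deleted), IV (31-36,
    short), III (>= 37, long), and ``unassigned`` for motif-free lengths
    18-30 where no natural population exists.
    """
    if length < 0:
        raise ValueError(f"negative pZBD length {length}")
    catalog = motifs.catalog_for(taxon)
    if motif_label != "none":
        names = [p.name for p in catalog]
        if motif_label not in names:
            raise ValueError(f"motif label {motif_label!r} not in {taxon} catalog")
        rank = names.index(motif_label)
        return "I" if rank == 0 else "II"
    if length <= 17:
        return "V"
    if 31 <= length <= 36:
        return "IV"
    if length >= 37:
        return "III"
    return "unassigned"


def annotate(records, anchors: AnchorSpec, taxon: str = "bacteria-GluRS") -> list[PZBDAnnotation]:
    """Full per-sequence annotation: window, length, motif label, group.

    Motif scanning is restricted to the pZBD window widened by
    ``SCAN_MARGIN`` residues on each side.
    """
    annots = extract_pzbd(records, anchors)
    catalog = motifs.catalog_for(taxon)
    for rec, ann in zip(records, annots):
        ungapped = "".join(c for c in str(rec.seq).upper() if c not in _GAP_CHARS)
        lo = max(0, ann.pzbd_start - SCAN_MARGIN)
        hi = min(len(ungapped), ann.pzbd_end + SCAN_MARGIN)
        hits = motifs.scan_sequence(ungapped, catalog, window=(lo, hi))
        ann.motif_label = motifs.classify_motif(hits, taxon)
        ann.group = assign_group(ann.length, ann.motif_label, taxon)
    return annots


def length_histogram(annotations, length_range: tuple[int, int] | None = None):
    """Per-length counts split by motif status.

    Returns ``{length: (with_motif, without_motif)}``.  When
    ``length_range=(lo, hi)`` is given, every length in [lo, hi] appears
    as a key even if its counts are zero.
    """
    annotations = list(annotations)
    if not annotations:
        raise ValueError("no annotations to histogram")
    hist: dict[int, list[int]] = {}
    if length_range is not None:
        lo, hi = length_range
        for length in range(lo, hi + 1):
            hist[length] = [0, 0]
    for ann in annotations:
        slot = hist.setdefault(ann.length, [0, 0])
        slot[0 if ann.motif_label != "none" else 1] += 1
    return {k: tuple(v) for k, v in sorted(hist.items())}
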