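"""Genomic co-occurrence logic for the indirect glutaminylation pathway.

In bacteria without glutaminyl-tRNA synthetase (GlnRS), Gln-tRNA(Gln) is
made indirectly: a non-discriminating GluRS misacylates tRNA(Gln) with
glutamate and the amidotransferase GatCAB transamidates it.  The pathway
becomes redundant once the genome carries GlnRS or a tRNA(Gln)-specific
second GluRS copy (GluRS2), and it is broken outright when gatCAB is
absent or tRNA(Gln) lacks the 1-72 acceptor-stem identity pair needed
for GatCAB recognition.  This module encodes the verdict logic per
genome and tests the deletion/direct-route association with an exact
2x2 contingency test (Fisher-style hypergeometric enumeration).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources

import pandas as pd

__all__ = [
    "GenomeContext",
    "PathwayVerdict",
    "evaluate_pathway",
    "contingency_test",
    "exact_2x2_p",
    "read_genome_table",
    "write_verdicts",
    "load_deleted_taxa_fixture",
]

_BASES = set("ACGU")


@dataclass(frozen=True)
class GenomeContext:
    """Per-genome presence/absence flags and the tRNA(Gln) 1/72 pair.

    ``trna_gln_1_72`` is two characters (e.g. ``"UA"`` for U1-A72), with
    ``"?"`` at either position when unknown.
    """

    genome_id: str
    has_glnrs: bool
    has_glurs2: bool
    has_gatcab: bool
    trna_gln_1_72: str = "??"
    pzbd_deleted: bool = False

    def __post_init__(self):
        pair = self.trna_gln_1_72.upper()
        if len(pair) != 2 or any(c not in _BASES | {"?"} for c in pair):
            raise ValueError(f"invalid 1/72 base pair {self.trna_gln_1_72!r}")
        object.__setattr__(self, "trna_gln_1_72", pair)

    @property
    def direct_gln_route(self) -> bool:
        return self.has_glnrs or self.has_glurs2


@dataclass(frozen=True)
class PathwayVerdict:
    genome_id: str
    direct_gln_route: bool
    indirect_route_intact: bool
    consistent: bool
    note: str = ""


def _pair_matches(pair: str, required: str, strict_orientation: bool) -> bool | None:
    """None when unknown; otherwise whether the 1/72 pair satisfies the
    recognition requirement.  By default orientation-insensitive (the
    literature writes the same recognition pair in both orders)."""
    if "?" in pair:
        return None
    if pair == required:
        return True
    if not strict_orientation and pair == required[::-1]:
        return True
    return False


def evaluate_pathway(
    ctx: GenomeContext,
    required_pair: str = "UA",
    strict_orientation: bool = False,
) -> PathwayVerdict:
    """Judge whether a genome is consistent with the deletion model.

    The model: a pZBD-deleted GluRS is tolerable only where the indirect
    glutaminylation pathway is redundant (GlnRS or GluRS2 present) or
    already disrupted (no gatCAB, or a tRNA(Gln) 1/72 pair that GatCAB
    cannot recognise).  Hence
    ``consistent = not pzbd_deleted or direct_gln_route or not indirect_route_intact``.

    An unknown 1/72 pair propagates conservatively: the indirect route is
    treated as intact and the verdict carries a note.
    """
    required = required_pair.upper()
    if len(required) != 2 or any(c not in _BASES for c in required):
        raise ValueError(f"invalid required base pair {required_pair!r}")
    notes = []
    match = _pair_matches(ctx.trna_gln_1_72, required, strict_orientation)
    if match is None:
        intact = ctx.has_gatcab
        if ctx.has_gatcab:
            notes.append("1/72 pair unknown; indirect route assumed intact")
    else:
        intact = ctx.has_gatcab and match
    consistent = (not ctx.pzbd_deleted) or ctx.direct_gln_route or (not intact)
    if not consistent:
        notes.append(
            "exception: pZBD-deleted with no direct Gln route and an intact indirect pathway"
        )
    return PathwayVerdict(
        genome_id=ctx.genome_id,
        direct_gln_route=ctx.direct_gln_route,
        indirect_route_intact=intact,
        consistent=consistent,
        note="; ".join(notes),
    )


def exact_2x2_p(table) -> float:
    """Two-sided exact p for a 2x2 table by hypergeometric enumeration.

    With margins fixed, every admissible table's probability is computed
    with exact integer binomial coefficients; the p-value is the sum of
    probabilities <= the observed table's (the usual two-sided Fisher
    convention, with an exact tie comparison).
    """
    (a, b), (c, d) = table
    if min(a, b, c, d) < 0:
        raise ValueError("negative cell count")
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    if n == 0:
        return 1.0
    denom = math.comb(n, c1)

    def weight(x):  # numerator of P(X = x), integer
        return math.comb(r1, x) * math.comb(r2, c1 - x)

    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    w_obs = weight(a)
    total = sum(w for x in range(lo, hi + 1) if (w := weight(x)) <= w_obs)
    return total / denom


def contingency_test(contexts, required_pair: str = "UA"):
    """2x2 association between pZBD deletion and a direct Gln route.

    Rows: pzbd_deleted (True, False); columns: direct_gln_route
    (True, False).  Returns ``(table, p)`` with the two-sided exact p
    from :func:`exact_2x2_p`.
    """
    contexts = list(contexts)
    if not contexts:
        raise ValueError("no genome contexts given")
    table = [[0, 0], [0, 0]]
    for ctx in contexts:
        i = 0 if ctx.pzbd_deleted else 1
        j = 0 if ctx.direct_gln_route else 1
        table[i][j] += 1
    return table, exact_2x2_p(table)


_BOOL = {"true": True, "1": True, "yes": True, "false": False, "0": False, "no": False}


def _to_bool(v) -> bool:
    if isinstance(v, bool):
        return v
    try:
        return _BOOL[str(v).strip().lower()]
    except KeyError:
        raise ValueError(f"cannot interpret {v!r} as boolean") from None


def read_genome_table(path_or_buf) -> list[GenomeContext]:
    """Read a genome flag table (TSV with header: genome_id, has_glnrs,
    has_glurs2, has_gatcab, trna_gln_1_72, pzbd_deleted)."""
    df = pd.read_csv(path_or_buf, sep="\t", dtype=str, comment="#")
    out = []
    for row in df.itertuples(index=False):
        out.append(
            GenomeContext(
                genome_id=str(row.genome_id),
                has_glnrs=_to_bool(row.has_glnrs),
                has_glurs2=_to_bool(row.has_glurs2),
                has_gatcab=_to_bool(row.has_gatcab),
                trna_gln_1_72=str(row.trna_gln_1_72),
                pzbd_deleted=_to_bool(row.pzbd_deleted),
            )
        )
    return out


def write_verdicts(verdicts, path):
    pd.DataFrame(
        [
            {
                "genome_id": v.genome_id,
                "direct_gln_route": v.direct_gln_route,
                "indirect_route_intact": v.indirect_route_intact,
                "consistent": v.consistent,
                "note": v.note,
            }
            for v in verdicts
        ]
    ).to_csv(path, sep="\t", index=False)


def load_deleted_taxa_fixture() -> list[GenomeContext]:
    """The seven pZBD-deleted bacterial taxa, encoded from published
    in-text genome annotations (six with GlnRS or GluRS2; the
    M. infernorum exception with neither, gatCAB present, and an A1-U72
    acceptor-stem pair)."""
    ref = resources.files("pzbd.data").joinpath("pzbd_deleted_taxa.tsv")
    with resources.as_file(ref) as path:
        return read_genome_table(path)
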