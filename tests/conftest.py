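"""Shared fixtures and independent oracle implementations.

The oracles deliberately use different algorithms from the package code
(recursive backtracking for motif matching, Fraction arithmetic for the
exact 2x2 test, generic numeric minimisation for superposition) so that
agreement is evidence, not tautology.
"""

from fractions import Fraction
from math import comb

import numpy as np
import pytest


def brute_force_motif_matches(seq: str, pattern):
    """All (anchored_positions, gaps) matches by recursive backtracking."""
    seq = seq.upper()
    n = len(seq)
    out = []

    def rec(anchor_idx, pos, anchored, gaps):
        if pos >= n or seq[pos] not in pattern.residue_sets[anchor_idx]:
            return
        anchored = anchored + [pos]
        if anchor_idx == len(pattern.residue_sets) - 1:
            out.append((tuple(anchored), tuple(gaps)))
            return
        lo, hi = pattern.gaps[anchor_idx]
        for g in range(lo, hi + 1):
            rec(anchor_idx + 1, pos + 1 + g, anchored, gaps + [g])

    for start in range(n):
        rec(0, start, [], [])
    return sorted(out)


def exact_2x2_p_fraction(table) -> Fraction:
    """Two-sided exact p by full margin-preserving enumeration with
    rational arithmetic (no floats until the caller converts)."""
    (a, b), (c, d) = table
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    if n == 0:
        return Fraction(1)
    denom = comb(n, c1)
    probs = {}
    for x in range(max(0, c1 - r2), min(r1, c1) + 1):
        probs[x] = Fraction(comb(r1, x) * comb(r2, c1 - x), denom)
    p_obs = probs[a]
    return sum((p for p in probs.values() if p <= p_obs), Fraction(0))


def random_rigid_transform(rng):
    """A uniform random rotation + translation pair."""
    from scipy.spatial.transform import Rotation

    R = Rotation.random(random_state=np.random.RandomState(rng.integers(2**31))).as_matrix()
    t = rng.normal(scale=20.0, size=3)
    return R, t


def transform_model(model, R, t):
    """Apply a rigid transform to every coordinate of a StructureModel."""
    from pzbd.geometry import Residue, StructureModel

    residues = [
        Residue(
            chain=r.chain,
            resnum=r.resnum,
            resname=r.resname,
            atoms={k: R @ v + t for k, v in r.atoms.items()},
        )
        for r in model.residues
    ]
    hetero = [(el, R @ xyz + t) for el, xyz in model.hetero_atoms]
    return StructureModel(residues=residues, hetero_atoms=hetero)


@pytest.fixture(scope="session")
def bacterial_catalog():
    from pzbd import motifs

    return motifs.catalog_for("bacteria-GluRS")


@pytest.fixture(scope="session")
def small_cohort():
    """A small mixed cohort generated once per session."""
    from pzbd import simulate

    spec = simulate.CohortSpec(
        n_per_group={"I": 6, "II": 3, "III": 6, "IV": 3, "V": 3}, seed=11
    )
    return simulate.gen_sequence_cohort(spec)
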