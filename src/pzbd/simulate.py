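"""Synthetic data generators with known ground truth.

Every input class the pipeline consumes can be generated here with a
planted, machine-readable truth: sequence cohorts with group-wise pZBD
lengths and planted (or guaranteed-absent) zinc-binding motifs, toy
coordinate sets with exact planted geometry, genome flag tables with a
tunable deletion/direct-route association, and noisy titration /
Michaelis-Menten / zinc-calibration series from the exact forward
models.  All generators are deterministic given (spec, seed).

Generator defaults mirror the study conditions: pZBD length ranges
46-54 (canonical), 31-36 (short) and 10-17 (deleted); titrations at
0.5 uM enzyme with Kd = 62.5 nM; glutamylation kinetics at
kcat = 5.3 s^-1, Km = 65.4 uM over 50-300 uM substrate; a zinc:protein
ratio of 0.93 at 10 uM protein.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from . import classify, kinetics, motifs
from .classify import AnchorSpec
from .genomes import GenomeContext

__all__ = [
    "CohortSpec",
    "GeometrySpec",
    "gen_sequence_cohort",
    "gen_structure",
    "gen_genome_table",
    "gen_titration",
    "gen_mm",
    "gen_zinc",
]

_AA = sorted(motifs.AMINO_ACIDS)

# fixed anchor beta-strand blocks flanking every synthetic pZBD
E3_BLOCK = "VRLRV"
E4_BLOCK = "ELTVR"
FLANK_LEN = 20

DEFAULT_LENGTH_RANGES = {
    "I": (46, 54),
    "II": (46, 54),
    "III": (46, 54),
    "IV": (31, 36),
    "V": (10, 17),
}


@dataclass(frozen=True)
class CohortSpec:
    """Composition of a synthetic sequence cohort."""

    n_per_group: dict
    length_ranges: dict = field(default_factory=lambda: dict(DEFAULT_LENGTH_RANGES))
    taxon: str = "bacteria-GluRS"
    seed: int = 0

    def __post_init__(self):
        for g, n in self.n_per_group.items():
            if g not in DEFAULT_LENGTH_RANGES:
                raise ValueError(f"unknown group {g!r}")
            if n < 0:
                raise ValueError("counts must be >= 0")


@dataclass(frozen=True)
class GeometrySpec:
    """One planted structural feature.

    ``kind`` is one of zn_site / hbond / tyr_i4_hbond / cation_pi;
    ``distance`` (A) and ``angle`` (deg, cation-pi only) set the exact
    planted geometry; ``ligand_summary`` (zn_site) gives the ligand
    composition in S/N/O counts, e.g. "S3N1"; ``separation`` (hbond)
    the ordinal residue separation of the partners.
    """

    kind: str
    distance: float = 2.3
    angle: float = 0.0
    chain_length: int = 30
    seed: int = 0
    ligand_summary: str = "S3N1"
    separation: int = 10

    def __post_init__(self):
        if self.kind not in {"zn_site", "hbond", "tyr_i4_hbond", "cation_pi"}:
            raise ValueError(f"unknown feature kind {self.kind!r}")
        if self.distance <= 0:
            raise ValueError("distance must be positive")
        if self.chain_length < 8:
            raise ValueError("chain_length too short")


def _random_background(rng, length: int) -> str:
    return "".join(rng.choice(_AA, size=length)) if length else ""


def _realise_pattern(rng, pattern: motifs.MotifPattern):
    """One concrete instance of a gapped pattern as (text, gap lengths)."""
    gaps = tuple(int(rng.integers(lo, hi + 1)) for lo, hi in pattern.gaps)
    parts = []
    for k, rs in enumerate(pattern.residue_sets):
        parts.append(rng.choice(sorted(rs)))
        if k < len(gaps):
            parts.append(_random_background(rng, gaps[k]))
    return "".join(parts), gaps


def _make_pzbd(rng, group: str, length: int, taxon: str, max_tries: int = 200):
    """A pZBD stretch whose classification is guaranteed by rejection
    against the scanner itself.  Returns (sequence, motif span or None)."""
    catalog = motifs.catalog_for(taxon)
    if group in ("I", "II"):
        rank = 0 if group == "I" else 1
        if rank >= len(catalog):
            raise ValueError(f"taxon {taxon} has no group-{group} pattern")
        pat = catalog[rank]
        if pat.min_span > length:
            raise ValueError(
                f"group {group} motif (span >= {pat.min_span}) cannot fit length {length}"
            )
    for _ in range(max_tries):
        if group in ("I", "II"):
            inst, _gaps = _realise_pattern(rng, pat)
            offset = int(rng.integers(0, length - len(inst) + 1))
            seq = (
                _random_background(rng, offset)
                + inst
                + _random_background(rng, length - offset - len(inst))
            )
            hits = motifs.scan_sequence(seq, catalog)
            if motifs.classify_motif(hits, taxon) == pat.name:
                return seq, (offset, offset + len(inst))
        else:
            seq = _random_background(rng, length)
            if not motifs.scan_sequence(seq, catalog):
                return seq, None
    raise RuntimeError(f"could not realise a group-{group} pZBD of length {length}")


def gen_sequence_cohort(spec: CohortSpec):
    """Generate a cohort of synthetic GluRS-like sequences.

    Each record is random background + E3 anchor block + a group-
    appropriate pZBD + E4 anchor block + background.  Returns
    ``(records, truth, aligned_records, anchors)`` where ``truth`` is a
    list of per-record dicts (group, length, motif coordinates within
    the full ungapped sequence) and the alignment pads every pZBD to the
    cohort maximum with gaps.
    """
    rng = np.random.default_rng(spec.seed)
    entries = []
    for group in ("I", "II", "III", "IV", "V"):
        n = spec.n_per_group.get(group, 0)
        lo, hi = spec.length_ranges.get(group, DEFAULT_LENGTH_RANGES[group])
        for _ in range(n):
            length = int(rng.integers(lo, hi + 1))
            pzbd, motif_span = _make_pzbd(rng, group, length, spec.taxon)
            entries.append((group, length, pzbd, motif_span))
    order = rng.permutation(len(entries))
    max_len = max((e[1] for e in entries), default=0)
    records, aligned, truth = [], [], []
    for new_idx, old_idx in enumerate(order):
        group, length, pzbd, motif_span = entries[old_idx]
        left = _random_background(rng, FLANK_LEN)
        right = _random_background(rng, FLANK_LEN)
        seq = left + E3_BLOCK + pzbd + E4_BLOCK + right
        seq_id = f"syn{new_idx:04d}"
        records.append(SeqRecord(Seq(seq), id=seq_id, description=f"group={group}"))
        aligned.append(
            SeqRecord(
                Seq(left + E3_BLOCK + pzbd + "-" * (max_len - length) + E4_BLOCK + right),
                id=seq_id,
                description="",
            )
        )
        pzbd_start = FLANK_LEN + len(E3_BLOCK)
        truth.append(
            {
                "seq_id": seq_id,
                "group": group,
                "length": length,
                "motif_start": pzbd_start + motif_span[0] if motif_span else -1,
                "motif_end": pzbd_start + motif_span[1] if motif_span else -1,
            }
        )
    anchors = AnchorSpec(
        e3_col=FLANK_LEN + len(E3_BLOCK) - 1,
        e4_col=FLANK_LEN + len(E3_BLOCK) + max_len,
    )
    return records, truth, aligned, anchors


# ---------------------------------------------------------------------------
# toy structures

_LIGAND_RESIDUES = {"S": ("CYS", "SG"), "N": ("HIS", "ND1"), "O": ("TYR", "OH")}


def _backbone(chain_length: int):
    """Extended poly-alanine backbone along x (no polar side chains, so
    no accidental detector hits)."""
    residues = []
    for i in range(chain_length):
        x = 3.8 * i
        residues.append(
            {
                "resname": "ALA",
                "resnum": i + 1,
                "atoms": {
                    "N": np.array([x, 0.0, 0.0]),
                    "CA": np.array([x + 1.2, 1.0, 0.0]),
                    "C": np.array([x + 2.4, 0.0, 0.0]),
                    "O": np.array([x + 2.4, -1.23, 0.0]),
                },
            }
        )
    return residues


def _format_pdb(residues, hetero=()):
    lines = []
    serial = 1
    for res in residues:
        for name, xyz in res["atoms"].items():
            pad_name = f" {name:<3s}" if len(name) < 4 else name
            lines.append(
                f"ATOM  {serial:5d} {pad_name}{'':1s}{res['resname']:>3s} A"
                f"{res['resnum']:4d}    {xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}"
                f"{1.00:6.2f}{0.00:6.2f}          {name[0]:>2s}"
            )
            serial += 1
    for el, xyz in hetero:
        lines.append(
            f"HETATM{serial:5d} {el:<4s}{'':1s}{el:>3s} Z{1:4d}    "
            f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}{1.00:6.2f}{0.00:6.2f}"
            f"          {el:>2s}"
        )
        serial += 1
    lines.append("END")
    return "\n".join(lines) + "\n"


def _tetrahedral_dirs():
    d = np.array(
        [[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]], dtype=float
    )
    return d / np.linalg.norm(d, axis=1, keepdims=True)


def _parse_ligand_summary(summary: str):
    import re

    out = []
    for el, cnt in re.findall(r"([SNO])(\d+)", summary):
        out.extend([el] * int(cnt))
    if not out or sum(1 for _ in out) > 4:
        raise ValueError(f"unsupported ligand summary {summary!r}")
    return out


def gen_structure(spec: GeometrySpec):
    """Emit PDB text with one feature planted at the exact target
    geometry, plus a truth record."""
    residues = _backbone(spec.chain_length)
    hetero = []
    truth = {"kind": spec.kind, "distance": spec.distance}
    if spec.kind == "zn_site":
        ligands = _parse_ligand_summary(spec.ligand_summary)
        if len(ligands) > spec.chain_length // 3:
            raise ValueError("chain too short for requested ligand count")
        zn = np.array([3.8 * spec.chain_length / 2, 10.0, 20.0])
        hetero.append(("ZN", zn))
        dirs = _tetrahedral_dirs()
        for k, el in enumerate(ligands):
            resname, atom = _LIGAND_RESIDUES[el]
            res = residues[3 * k + 2]
            res["resname"] = resname
            res["atoms"][atom] = zn + spec.distance * dirs[k]
        truth["summary"] = spec.ligand_summary
    elif spec.kind == "hbond":
        i, j = 5, 5 + spec.separation
        if j >= spec.chain_length:
            raise ValueError("separation exceeds chain length")
        residues[i]["resname"] = "SER"
        # place OG below the acceptor O, away from neighbouring backbone N/O
        og = residues[j]["atoms"]["O"] + np.array([0.0, -spec.distance, 0.0])
        residues[i]["atoms"]["OG"] = og
        truth.update(donor=(i + 1, "OG"), acceptor=(j + 1, "O"), separation=spec.separation)
    elif spec.kind == "tyr_i4_hbond":
        i = 5
        residues[i]["resname"] = "TYR"
        oh = residues[i + 4]["atoms"]["N"] + np.array([0.0, 0.0, spec.distance])
        residues[i]["atoms"]["OH"] = oh
        truth.update(tyr=i + 1, partner=i + 5)
    elif spec.kind == "cation_pi":
        i, j = 5, 12
        if j >= spec.chain_length:
            raise ValueError("chain too short")
        ring_centroid = np.array([3.8 * i, 6.0, 10.0])
        residues[i]["resname"] = "TYR"
        ring_names = ("CG", "CD1", "CE1", "CZ", "CE2", "CD2")
        for k, name in enumerate(ring_names):
            th = 2 * np.pi * k / 6
            residues[i]["atoms"][name] = ring_centroid + 1.39 * np.array(
                [np.cos(th), np.sin(th), 0.0]
            )
        theta = np.radians(spec.angle)
        direction = np.array([np.sin(theta), 0.0, np.cos(theta)])
        gcen = ring_centroid + spec.distance * direction
        residues[j]["resname"] = "ARG"
        # small guanidinium triangle centred exactly on gcen
        offsets = [np.array([0.0, 0.66, 0.0]), np.array([0.57, -0.33, 0.0]), np.array([-0.57, -0.33, 0.0])]
        for name, off in zip(("CZ", "NH1", "NH2"), offsets):
            residues[j]["atoms"][name] = gcen + off
        truth.update(angle=spec.angle, arg=j + 1, aromatic=i + 1)
    return _format_pdb(residues, hetero), truth


# ---------------------------------------------------------------------------
# genome tables

_NON_RECOGNITION_PAIRS = ("GC", "CG", "AC")


def gen_genome_table(
    n: int,
    p_deleted: float = 0.3,
    odds_ratio: float = 1.0,
    seed: int = 0,
    p_direct_base: float = 0.5,
):
    """Sample genome flag tables with a tunable deletion/direct-route
    association.

    ``pzbd_deleted ~ Bernoulli(p_deleted)``; the direct-route flag uses
    baseline probability ``p_direct_base`` for pZBD-containing genomes
    and odds scaled by ``odds_ratio`` for deleted ones.  Genomes without
    a direct route are given an intact indirect pathway (gatCAB plus a
    U1-A72 pair) so every genome retains a Gln-tRNA(Gln) source; direct-
    route genomes carry gatCAB and recognition pairs at random.
    Returns ``(contexts, truth)``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    for name, p in [("p_deleted", p_deleted), ("p_direct_base", p_direct_base)]:
        if not 0 <= p <= 1:
            raise ValueError(f"{name} must be in [0, 1]")
    if odds_ratio <= 0:
        raise ValueError("odds_ratio must be positive")
    rng = np.random.default_rng(seed)
    base_odds = p_direct_base / (1 - p_direct_base) if p_direct_base < 1 else np.inf
    odds_del = odds_ratio * base_odds
    p_direct_del = odds_del / (1 + odds_del) if np.isfinite(odds_del) else 1.0
    contexts = []
    table = [[0, 0], [0, 0]]
    for k in range(n):
        deleted = bool(rng.random() < p_deleted)
        p_dir = p_direct_del if deleted else p_direct_base
        direct = bool(rng.random() < p_dir)
        if direct:
            has_glnrs = bool(rng.random() < 0.7)
            has_glurs2 = not has_glnrs or bool(rng.random() < 0.1)
            has_gatcab = bool(rng.random() < 0.5)
            pair = "UA" if (has_gatcab and rng.random() < 0.5) else str(rng.choice(_NON_RECOGNITION_PAIRS))
        else:
            has_glnrs = has_glurs2 = False
            has_gatcab = True
            pair = "UA"
        contexts.append(
            GenomeContext(
                genome_id=f"g{k:04d}",
                has_glnrs=has_glnrs,
                has_glurs2=has_glurs2,
                has_gatcab=has_gatcab,
                trna_gln_1_72=pair,
                pzbd_deleted=deleted,
            )
        )
        table[0 if deleted else 1][0 if direct else 1] += 1
    truth = {
        "p_deleted": p_deleted,
        "odds_ratio": odds_ratio,
        "p_direct_base": p_direct_base,
        "table": table,
    }
    return contexts, truth


# ---------------------------------------------------------------------------
# titration / kinetics / zinc series

# 24 ligand additions: dense through the stoichiometric transition around
# the 0.5 uM enzyme concentration, sparser towards saturation
DEFAULT_LIGAND_CONCS = np.concatenate(
    [np.linspace(0.0, 0.9, 19), [1.1, 1.4, 1.8, 2.2, 2.6]]
) * 1e-6  # M

DEFAULT_SUBSTRATE_CONCS = np.array([50, 75, 100, 125, 150, 200, 250, 300]) * 1e-6  # M


def _apply_noise(rng, y, noise: float):
    if noise < 0:
        raise ValueError("noise must be >= 0")
    if noise == 0:
        return np.asarray(y, dtype=float)
    return np.asarray(y, dtype=float) * (1.0 + noise * rng.standard_normal(len(y)))


def gen_titration(
    kd: float = 62.5e-9,
    enzyme_conc: float = 0.5e-6,
    ligand_concs=None,
    amplitude: float = -60.0,
    baseline: float = 100.0,
    noise: float = 0.0,
    seed: int = 0,
):
    """Simulate a fluorescence-quenching titration from the exact
    depletion-aware 1:1 model plus multiplicative Gaussian noise."""
    rng = np.random.default_rng(seed)
    L = np.asarray(DEFAULT_LIGAND_CONCS if ligand_concs is None else ligand_concs, dtype=float)
    y = kinetics.binding_signal(L, enzyme_conc, kd, amplitude, baseline)
    series = kinetics.TitrationSeries(
        enzyme_conc=enzyme_conc,
        ligand_concs=L,
        signal=_apply_noise(rng, y, noise),
        ligand_name="tRNA-Glu",
    )
    truth = {"kd": kd, "amplitude": amplitude, "baseline": baseline, "noise": noise}
    return series, truth


def gen_mm(
    kcat: float = 5.3,
    km: float = 65.4e-6,
    enzyme_conc: float = 50e-9,
    substrate_concs=None,
    noise: float = 0.0,
    seed: int = 0,
):
    """Simulate a Michaelis-Menten initial-rate series."""
    rng = np.random.default_rng(seed)
    S = np.asarray(DEFAULT_SUBSTRATE_CONCS if substrate_concs is None else substrate_concs, dtype=float)
    v = kinetics.mm_rate(S, enzyme_conc, kcat, km)
    series = kinetics.KineticsSeries(
        enzyme_conc=enzyme_conc,
        substrate_concs=S,
        rates=_apply_noise(rng, v, noise),
    )
    truth = {"kcat": kcat, "km": km, "noise": noise}
    return series, truth


def gen_zinc(
    ratio: float = 0.93,
    protein_conc: float = 10e-6,
    slope: float = 0.05e6,  # A500 per M Zn
    intercept: float = 0.0,
    background: float = 0.05,
    standard_concs=None,
    noise: float = 0.0,
    seed: int = 0,
):
    """Simulate a PAR zinc calibration and a sample at a known
    Zn:protein ratio."""
    rng = np.random.default_rng(seed)
    zn = np.asarray(
        np.array([0, 2, 4, 6, 8, 12]) * 1e-6 if standard_concs is None else standard_concs,
        dtype=float,
    )
    a = _apply_noise(rng, slope * zn + intercept, noise)
    zn_sample = ratio * protein_conc
    plateau = background + slope * zn_sample + intercept
    assay = kinetics.ZincAssay(
        standards=list(zip(zn.tolist(), a.tolist())),
        sample_a500_background=background,
        sample_a500_plateau=plateau,
        protein_conc=protein_conc,
    )
    truth = {"ratio": ratio, "slope": slope, "intercept": intercept, "noise": noise}
    return assay, truth
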