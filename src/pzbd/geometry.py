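"""Geometric feature detection in protein structures.

Detects, from 3D coordinates, the features that distinguish zinc-bound
from zinc-free pZBDs in glutamyl-tRNA synthetases: the Zn2+ coordination
sphere (e.g. three sulfur + one nitrogen ligands), side-chain-mediated
long-range hydrogen bonds, the conserved H-bond between a tyrosine
phenolic oxygen and the (i+4)-th backbone nitrogen, and arginine-aromatic
cation-pi contacts.  Also provides anchored rigid-body superposition
(optimal least-squares rotation) with RMSD.

Thresholds (2.8 A Zn-ligand, 3.5 A H-bond, 6.0 A / 45 deg cation-pi) are
standard structural-biology practice and are exposed as parameters.
Hydrogens are ignored throughout; donor/acceptor chemistry is a
simplified heavy-atom N/O tabulation per residue type.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

__all__ = [
    "StructureModel",
    "Residue",
    "InteractionRecord",
    "read_structure",
    "detect_zn_site",
    "detect_hbonds",
    "detect_tyr_i4_hbond",
    "detect_cation_pi",
    "superpose",
]

ZN_CUTOFF = 2.8
HBOND_DMAX = 3.5
LONG_RANGE_MIN_SEP = 5
CATION_PI_DMAX = 6.0
CATION_PI_MAX_ANGLE = 45.0

_BACKBONE = {"N", "CA", "C", "O", "OXT"}

# Simplified heavy-atom H-bond chemistry: atoms able to donate (carry a
# polar H) and accept.  Backbone N donates, backbone O accepts, for every
# residue type.
_SIDECHAIN_DONORS = {
    "SER": {"OG"}, "THR": {"OG1"}, "TYR": {"OH"}, "ASN": {"ND2"},
    "GLN": {"NE2"}, "LYS": {"NZ"}, "ARG": {"NE", "NH1", "NH2"},
    "HIS": {"ND1", "NE2"}, "TRP": {"NE1"},
}
_SIDECHAIN_ACCEPTORS = {
    "ASP": {"OD1", "OD2"}, "GLU": {"OE1", "OE2"}, "ASN": {"OD1"},
    "GLN": {"OE1"}, "SER": {"OG"}, "THR": {"OG1"}, "TYR": {"OH"},
    "HIS": {"ND1", "NE2"},
}

# Six-membered aromatic ring atoms used for cation-pi centroids.
_AROMATIC_RINGS = {
    "TYR": ("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "PHE": ("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "TRP": ("CD2", "CE2", "CE3", "CZ2", "CZ3", "CH2"),
}


@dataclass
class Residue:
    chain: str
    resnum: int
    resname: str
    atoms: dict  # atom name -> np.ndarray(3,)

    def get(self, name):
        return self.atoms.get(name)


@dataclass
class StructureModel:
    """Ordered residues plus hetero atoms (Zn etc.) of one model."""

    residues: list
    hetero_atoms: list = field(default_factory=list)  # (element, coord)

    def chain(self, chain_id: str) -> "StructureModel":
        """Restrict to a single chain (hetero atoms kept)."""
        return StructureModel(
            residues=[r for r in self.residues if r.chain == chain_id],
            hetero_atoms=list(self.hetero_atoms),
        )

    def chains(self):
        seen = []
        for r in self.residues:
            if r.chain not in seen:
                seen.append(r.chain)
        return seen

    @property
    def zn_atoms(self):
        return [xyz for el, xyz in self.hetero_atoms if el.upper() == "ZN"]


@dataclass(frozen=True)
class InteractionRecord:
    """One detected geometric feature.

    ``partners`` holds (chain, resnum, atom-or-descriptor) tuples;
    ``seq_separation`` is the |i-j| ordinal residue-index separation
    within a chain (insertion-code-safe), not author numbering.
    """

    kind: str  # hbond | tyr_i4_hbond | cation_pi | zn_ligand
    partners: tuple
    distance: float
    angle: float | None = None
    seq_separation: int | None = None
    long_range: bool = False


def _validate_pdb_lines(pdb_text: str):
    n_atom = 0
    for lineno, line in enumerate(pdb_text.splitlines(), start=1):
        if line.startswith(("ATOM  ", "HETATM")):
            n_atom += 1
            try:
                float(line[30:38]); float(line[38:46]); float(line[46:54])
                int(line[22:26])
            except (ValueError, IndexError):
                raise ValueError(f"malformed fixed-width PDB record at line {lineno}")
    if n_atom == 0:
        raise ValueError("no ATOM/HETATM records in PDB input")


def read_structure(pdb_text: str) -> StructureModel:
    """Parse PDB-format text into a :class:`StructureModel`.

    Only the first MODEL is used; for alternate locations a single
    coordinate set is retained (highest occupancy, then altloc 'A').
    Raises ``ValueError`` when no ATOM records are present or a
    fixed-width record is malformed (the message names the line).
    """
    from Bio.PDB import PDBParser

    _validate_pdb_lines(pdb_text)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        parser = PDBParser(QUIET=True)
        structure = parser.get_structure("m", io.StringIO(pdb_text))
    model = next(iter(structure))  # first MODEL
    residues: list[Residue] = []
    hetero: list[tuple] = []
    for chain in model:
        for res in chain:
            het_flag = res.id[0]
            atoms = {}
            for atom in res:  # DisorderedAtom yields its selected child
                atoms[atom.get_name()] = np.asarray(atom.get_coord(), dtype=float)
            if het_flag.strip():  # HETATM (water, ions, ligands)
                for atom in res:
                    el = atom.element or atom.get_name()
                    hetero.append((el.strip().upper(), np.asarray(atom.get_coord(), dtype=float)))
            else:
                residues.append(
                    Residue(chain=chain.id, resnum=res.id[1], resname=res.get_resname(), atoms=atoms)
                )
    if not residues and not hetero:
        raise ValueError("no ATOM/HETATM records in PDB input")
    return StructureModel(residues=residues, hetero_atoms=hetero)


def _dist(a, b) -> float:
    return float(np.linalg.norm(np.asarray(a) - np.asarray(b)))


def detect_zn_site(model: StructureModel, cutoff: float = ZN_CUTOFF):
    """Zinc coordination spheres.

    For each Zn hetero atom, every candidate ligand atom (Cys SG, His
    ND1/NE2, Tyr OH, and any other backbone or side-chain N/O) within
    ``cutoff`` is reported.  Returns ``(records, summaries)`` where
    ``summaries[k]`` counts ligand elements of the k-th Zn in S/N/O
    order, e.g. ``"S3N1"`` (empty string for an unligated Zn).  A model
    without Zn yields empty results.
    """
    records: list[InteractionRecord] = []
    summaries: list[str] = []
    for zi, zn in enumerate(model.zn_atoms):
        counts = {"S": 0, "N": 0, "O": 0}
        for res in model.residues:
            for name, xyz in res.atoms.items():
                el = name[0]
                if el == "S" and not (res.resname == "CYS" and name == "SG"):
                    continue  # only cysteine thiolate sulfur coordinates
                if el not in counts:
                    continue
                d = _dist(zn, xyz)
                if d <= cutoff:
                    counts[el] += 1
                    records.append(
                        InteractionRecord(
                            kind="zn_ligand",
                            partners=(("ZN", zi, "ZN"), (res.chain, res.resnum, name)),
                            distance=d,
                        )
                    )
        summaries.append("".join(f"{el}{counts[el]}" for el in ("S", "N", "O") if counts[el]))
    return records, summaries


def _indexed_residues(model):
    """Per-chain ordinal index (insertion-safe sequence separation)."""
    idx = {}
    counters: dict[str, int] = {}
    for res in model.residues:
        k = counters.get(res.chain, 0)
        idx[id(res)] = k
        counters[res.chain] = k + 1
    return idx


def detect_hbonds(
    model: StructureModel,
    dmax: float = HBOND_DMAX,
    long_range_min_sep: int = LONG_RANGE_MIN_SEP,
) -> list[InteractionRecord]:
    """Side-chain-mediated hydrogen bonds by heavy-atom geometry.

    Donor-acceptor N/O pairs from different residues, with at least one
    side-chain atom, at distance <= ``dmax``.  A bond is flagged
    ``long_range`` iff the ordinal residue separation |i-j| within a
    chain is >= ``long_range_min_sep`` (inter-chain bonds are always
    long-range in spirit but keep ``seq_separation=None``).
    """
    idx = _indexed_residues(model)
    donors, acceptors = [], []
    for res in model.residues:
        for name in res.atoms:
            if name == "N":
                donors.append((res, name))
            elif name == "O":
                acceptors.append((res, name))
            else:
                if name in _SIDECHAIN_DONORS.get(res.resname, ()):
                    donors.append((res, name))
                if name in _SIDECHAIN_ACCEPTORS.get(res.resname, ()):
                    acceptors.append((res, name))
    records = []
    seen = set()
    for dres, datom in donors:
        for ares, aatom in acceptors:
            if dres is ares:
                continue
            if datom in _BACKBONE and aatom in _BACKBONE:
                continue  # at least one side-chain atom required
            key = frozenset([(id(dres), datom), (id(ares), aatom)])
            if key in seen:
                continue
            d = _dist(dres.atoms[datom], ares.atoms[aatom])
            if d > dmax:
                continue
            seen.add(key)
            if dres.chain == ares.chain:
                sep = abs(idx[id(dres)] - idx[id(ares)])
            else:
                sep = None
            records.append(
                InteractionRecord(
                    kind="hbond",
                    partners=((dres.chain, dres.resnum, datom), (ares.chain, ares.resnum, aatom)),
                    distance=d,
                    seq_separation=sep,
                    long_range=(sep is None or sep >= long_range_min_sep),
                )
            )
    return records


def detect_tyr_i4_hbond(model: StructureModel, dmax: float = HBOND_DMAX) -> list[InteractionRecord]:
    """Conserved Tyr OH ... backbone N(i+4) hydrogen bond.

    For every tyrosine at ordinal position i within a chain whose
    phenolic oxygen lies within ``dmax`` of the backbone nitrogen of
    residue i+4 in the same chain, emit a record.
    """
    records = []
    by_chain: dict[str, list] = {}
    for res in model.residues:
        by_chain.setdefault(res.chain, []).append(res)
    for chain_residues in by_chain.values():
        for i, res in enumerate(chain_residues):
            if res.resname != "TYR" or "OH" not in res.atoms:
                continue
            if i + 4 >= len(chain_residues):
                continue
            partner = chain_residues[i + 4]
            if "N" not in partner.atoms:
                continue
            d = _dist(res.atoms["OH"], partner.atoms["N"])
            if d <= dmax:
                records.append(
                    InteractionRecord(
                        kind="tyr_i4_hbond",
                        partners=((res.chain, res.resnum, "OH"), (partner.chain, partner.resnum, "N")),
                        distance=d,
                        seq_separation=4,
                    )
                )
    return records


def _ring_geometry(res: Residue):
    names = _AROMATIC_RINGS.get(res.resname)
    if names is None:
        return None
    try:
        coords = np.array([res.atoms[n] for n in names])
    except KeyError:
        warnings.warn(
            f"{res.resname} {res.chain}{res.resnum}: missing ring atoms, skipped",
            stacklevel=2,
        )
        return None
    centroid = coords.mean(axis=0)
    # best-fit plane normal: singular vector of the smallest singular value
    _, _, vt = np.linalg.svd(coords - centroid)
    return centroid, vt[2]


def detect_cation_pi(
    model: StructureModel,
    dmax: float = CATION_PI_DMAX,
    max_angle: float = CATION_PI_MAX_ANGLE,
) -> list[InteractionRecord]:
    """Arginine guanidinium vs aromatic ring (Tyr/Phe/Trp) contacts.

    Criteria: guanidinium centroid (CZ, NH1, NH2 mean) within ``dmax`` of
    the six-ring centroid, and the angle between the ring normal and the
    centroid-to-cation vector at most ``max_angle`` degrees (face-on
    geometry; edge-on approaches are rejected).
    """
    idx = _indexed_residues(model)
    args, aromatics = [], []
    for res in model.residues:
        if res.resname == "ARG":
            try:
                cen = np.mean([res.atoms[n] for n in ("CZ", "NH1", "NH2")], axis=0)
            except KeyError:
                warnings.warn(f"ARG {res.chain}{res.resnum}: missing guanidinium atoms, skipped", stacklevel=2)
                continue
            args.append((res, cen))
        elif res.resname in _AROMATIC_RINGS:
            geom = _ring_geometry(res)
            if geom is not None:
                aromatics.append((res, *geom))
    records = []
    for ares, acen in args:
        for rres, rcen, normal in aromatics:
            if ares is rres:
                continue
            v = acen - rcen
            d = float(np.linalg.norm(v))
            if d == 0 or d > dmax:
                continue
            cosang = abs(float(np.dot(v / d, normal)))
            angle = float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))
            if angle > max_angle:
                continue
            sep = abs(idx[id(ares)] - idx[id(rres)]) if ares.chain == rres.chain else None
            records.append(
                InteractionRecord(
                    kind="cation_pi",
                    partners=(
                        (ares.chain, ares.resnum, "guanidinium"),
                        (rres.chain, rres.resnum, "ring-centroid"),
                    ),
                    distance=d,
                    angle=angle,
                    seq_separation=sep,
                )
            )
    return records


def superpose(coords_a, coords_b):
    """Least-squares rigid superposition of matched coordinate lists.

    Finds the proper rotation R and translation t minimising
    ``|| a - (R b + t) ||``; returns ``(R, t, rmsd)``.

    Raises ``ValueError`` for fewer than 3 points or collinear points
    (where the rotation is not uniquely determined).
    """
    a = np.asarray(coords_a, dtype=float)
    b = np.asarray(coords_b, dtype=float)
    if a.shape != b.shape or a.ndim != 2 or a.shape[1] != 3:
        raise ValueError("matched (n, 3) coordinate arrays required")
    n = a.shape[0]
    if n < 3:
        raise ValueError("at least 3 points required for superposition")
    ca, cb = a.mean(axis=0), b.mean(axis=0)
    a0, b0 = a - ca, b - cb
    if np.linalg.matrix_rank(a0, tol=1e-8) < 2 or np.linalg.matrix_rank(b0, tol=1e-8) < 2:
        raise ValueError("collinear points: superposition is degenerate")
    rot, _ = Rotation.align_vectors(a0, b0)
    R = rot.as_matrix()
    t = ca - R @ cb
    # recompute the RMSD from the fitted coordinates (full precision,
    # rather than the solver's reported residual)
    rmsd = float(np.sqrt(np.mean(np.sum((a0 - b0 @ R.T) ** 2, axis=1))))
    return R, t, rmsd
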