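"""Structure parsing, feature detectors and rigid superposition."""

import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from conftest import random_rigid_transform, transform_model
from pzbd import geometry, simulate
from pzbd.geometry import read_structure, superpose
from pzbd.simulate import GeometrySpec, gen_structure

TOY_PDB = """\
ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  ALA A   1       1.200   1.000   0.000  1.00  0.00           C
ATOM      3  C   ALA A   1       2.400   0.000   0.000  1.00  0.00           C
END
"""

ZN_PDB = TOY_PDB.replace(
    "END\n",
    "HETATM    4 ZN    ZN Z   1       5.000   5.000   5.000  1.00  0.00          ZN\nEND\n",
)


def _altloc_pdb(first, second):
    """Ser OG with two altlocs in a given order (occupancies 0.7/0.3)."""
    lines = [
        "ATOM      1  N   SER A   1       0.000   0.000   0.000  1.00  0.00           N",
        "ATOM      2  CA  SER A   1       1.200   1.000   0.000  1.00  0.00           C",
        f"ATOM      3  OG {first[0]}SER A   1  {first[1]:10.3f}   0.000   0.000{first[2]:6.2f}  0.00           O",
        f"ATOM      4  OG {second[0]}SER A   1  {second[1]:10.3f}   0.000   0.000{second[2]:6.2f}  0.00           O",
        "END",
    ]
    return "\n".join(lines) + "\n"


class TestReadStructure:
    def test_minimal_model(self):
        m = read_structure(TOY_PDB)
        assert len(m.residues) == 1
        assert set(m.residues[0].atoms) == {"N", "CA", "C"}
        np.testing.assert_allclose(m.residues[0].atoms["CA"], [1.2, 1.0, 0.0])

    def test_hetatm_zn(self):
        m = read_structure(ZN_PDB)
        assert len(m.zn_atoms) == 1
        np.testing.assert_allclose(m.zn_atoms[0], [5.0, 5.0, 5.0])

    def test_altloc_highest_occupancy_order_independent(self):
        a = read_structure(_altloc_pdb(("A", 3.0, 0.70), ("B", 9.0, 0.30)))
        b = read_structure(_altloc_pdb(("B", 9.0, 0.30), ("A", 3.0, 0.70)))
        xa = a.residues[0].atoms["OG"]
        xb = b.residues[0].atoms["OG"]
        np.testing.assert_allclose(xa, xb)
        assert xa[0] == pytest.approx(3.0)  # the 0.70-occupancy conformer

    def test_no_atoms_rejected(self):
        with pytest.raises(ValueError, match="no ATOM"):
            read_structure("HEADER junk\nEND\n")

    def test_malformed_line_names_line_number(self):
        bad = TOY_PDB.replace("       1.200", "        abc ")
        with pytest.raises(ValueError, match="line 2"):
            read_structure(bad)


class TestZnSite:
    @pytest.mark.parametrize("summary, dist", [("S3N1", 2.3), ("S3O1", 2.2), ("S2N2", 2.1)])
    def test_planted_coordination_recovered(self, summary, dist):
        pdb, truth = gen_structure(GeometrySpec(kind="zn_site", ligand_summary=summary, distance=dist))
        records, summaries = geometry.detect_zn_site(read_structure(pdb))
        assert summaries == [summary]
        assert all(abs(r.distance - dist) < 1e-3 for r in records)

    def test_ligand_outside_cutoff_ignored(self):
        pdb, _ = gen_structure(GeometrySpec(kind="zn_site", ligand_summary="S3N1", distance=3.5))
        _, summaries = geometry.detect_zn_site(read_structure(pdb))
        assert summaries == [""]

    def test_no_zn_is_empty_not_error(self):
        records, summaries = geometry.detect_zn_site(read_structure(TOY_PDB))
        assert records == [] and summaries == []


class TestHbonds:
    def test_planted_long_range(self):
        pdb, _ = gen_structure(GeometrySpec(kind="hbond", distance=2.9, separation=10))
        recs = geometry.detect_hbonds(read_structure(pdb))
        assert len(recs) == 1
        assert recs[0].distance == pytest.approx(2.9, abs=1e-3)
        assert recs[0].seq_separation == 10 and recs[0].long_range

    def test_short_separation_not_long_range(self):
        pdb, _ = gen_structure(GeometrySpec(kind="hbond", distance=2.9, separation=2))
        recs = geometry.detect_hbonds(read_structure(pdb))
        assert len(recs) == 1
        assert not recs[0].long_range

    def test_boundary_separation_is_long_range(self):
        # "more than four residues apart" means |i - j| >= 5
        for sep, expected in [(4, False), (5, True)]:
            pdb, _ = gen_structure(GeometrySpec(kind="hbond", distance=2.9, separation=sep))
            recs = geometry.detect_hbonds(read_structure(pdb))
            assert recs[0].long_range is expected

    def test_beyond_dmax_absent(self):
        pdb, _ = gen_structure(GeometrySpec(kind="hbond", distance=3.8))
        assert geometry.detect_hbonds(read_structure(pdb)) == []

    def test_just_past_threshold_absent(self):
        pdb, _ = gen_structure(GeometrySpec(kind="hbond", distance=3.6))
        assert geometry.detect_hbonds(read_structure(pdb), dmax=3.5) == []


class TestTyrI4:
    def test_planted_detected(self):
        pdb, _ = gen_structure(GeometrySpec(kind="tyr_i4_hbond", distance=2.9))
        recs = geometry.detect_tyr_i4_hbond(read_structure(pdb))
        assert len(recs) == 1
        assert recs[0].seq_separation == 4
        assert recs[0].partners[1][1] - recs[0].partners[0][1] == 4

    def test_wrong_offset_not_detected(self):
        pdb, _ = gen_structure(GeometrySpec(kind="tyr_i4_hbond", distance=2.9))
        m = read_structure(pdb)
        # move the planted OH next to the i+3 backbone N instead
        for res in m.residues:
            if res.resname == "TYR":
                i = m.residues.index(res)
                res.atoms["OH"] = m.residues[i + 3].atoms["N"] + np.array([0, 0, 2.9])
        assert geometry.detect_tyr_i4_hbond(m) == []

    def test_two_tyrosines_two_records(self):
        pdb, _ = gen_structure(GeometrySpec(kind="tyr_i4_hbond", distance=2.9))
        m = read_structure(pdb)
        donor = [r for r in m.residues if r.resname == "TYR"][0]
        j = m.residues.index(donor) + 10
        m.residues[j].resname = "TYR"
        m.residues[j].atoms["OH"] = m.residues[j + 4].atoms["N"] + np.array([0, 0, 3.0])
        recs = geometry.detect_tyr_i4_hbond(m)
        assert len(recs) == 2


class TestCationPi:
    def test_planted_face_on_detected(self):
        pdb, _ = gen_structure(GeometrySpec(kind="cation_pi", distance=4.2, angle=10.0))
        recs = geometry.detect_cation_pi(read_structure(pdb))
        assert len(recs) == 1
        assert recs[0].distance == pytest.approx(4.2, abs=1e-3)
        assert recs[0].angle == pytest.approx(10.0, abs=0.1)

    def test_edge_on_rejected(self):
        pdb, _ = gen_structure(GeometrySpec(kind="cation_pi", distance=4.2, angle=80.0))
        assert geometry.detect_cation_pi(read_structure(pdb)) == []

    def test_arg_phe_pair_detected(self):
        pdb, _ = gen_structure(GeometrySpec(kind="cation_pi", distance=4.5, angle=5.0))
        m = read_structure(pdb)
        for res in m.residues:
            if res.resname == "TYR":
                res.resname = "PHE"
        recs = geometry.detect_cation_pi(m)
        assert len(recs) == 1 and recs[0].partners[1][1] is not None

    def test_missing_ring_atoms_skipped_with_warning(self):
        pdb, _ = gen_structure(GeometrySpec(kind="cation_pi", distance=4.2, angle=10.0))
        m = read_structure(pdb)
        for res in m.residues:
            if res.resname == "TYR":
                del res.atoms["CZ"]
        with pytest.warns(UserWarning, match="ring"):
            assert geometry.detect_cation_pi(m) == []


class TestSuperpose:
    def test_identity(self):
        rng = np.random.default_rng(0)
        a = rng.normal(size=(10, 3))
        R, t, rmsd = superpose(a, a)
        np.testing.assert_allclose(R, np.eye(3), atol=1e-9)
        np.testing.assert_allclose(t, 0, atol=1e-9)
        assert rmsd < 1e-9

    def test_rigid_copy_recovers_zero_rmsd(self):
        rng = np.random.default_rng(1)
        a = rng.normal(size=(12, 3)) * 5
        Rt, tt = random_rigid_transform(rng)
        b = a @ Rt.T + tt
        R, t, rmsd = superpose(a, b)
        assert rmsd < 1e-6
        assert np.linalg.det(R) == pytest.approx(1.0, abs=1e-9)
        np.testing.assert_allclose(a, b @ R.T + t, atol=1e-6)

    def test_symmetry_of_rmsd(self):
        rng = np.random.default_rng(2)
        a = rng.normal(size=(8, 3))
        b = a + rng.normal(scale=0.3, size=(8, 3))
        assert superpose(a, b)[2] == pytest.approx(superpose(b, a)[2], abs=1e-9)

    def test_single_displaced_atom_matches_numeric_minimisation(self):
        """One atom displaced by 1 A among 10: RMSD after re-fit is at
        most sqrt(1/10) and equals a generic numeric minimiser's value."""
        rng = np.random.default_rng(3)
        a = rng.normal(size=(10, 3)) * 4
        b = a.copy()
        b[0] += np.array([1.0, 0.0, 0.0])
        _, _, rmsd = superpose(a, b)
        assert rmsd <= np.sqrt(1 / 10) + 1e-12

        def objective(x):
            R = Rotation.from_rotvec(x[:3]).as_matrix()
            return np.sqrt(np.mean(np.sum((a - (b @ R.T + x[3:])) ** 2, axis=1)))

        best = min(
            (
                minimize(objective, np.concatenate([rv, tv]), method="Nelder-Mead",
                         options={"xatol": 1e-10, "fatol": 1e-14, "maxiter": 20000})
                for rv in (np.zeros(3), np.array([0.05, 0, 0]))
                for tv in (np.zeros(3), a.mean(0) - b.mean(0))
            ),
            key=lambda r: r.fun,
        )
        assert rmsd == pytest.approx(best.fun, abs=1e-6)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            superpose([[0, 0, 0], [1, 0, 0]], [[0, 0, 0], [1, 0, 0]])
        line = [[0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]]
        with pytest.raises(ValueError, match="collinear"):
            superpose(line, line)


def _all_feature_models():
    specs = [
        GeometrySpec(kind="zn_site", ligand_summary="S3N1", distance=2.3),
        GeometrySpec(kind="hbond", distance=2.9, separation=10),
        GeometrySpec(kind="tyr_i4_hbond", distance=2.9),
        GeometrySpec(kind="cation_pi", distance=4.2, angle=10.0),
    ]
    return [read_structure(gen_structure(s)[0]) for s in specs]


def _feature_signature(model):
    import warnings as _w

    with _w.catch_warnings():
        _w.simplefilter("ignore")
        recs, summaries = geometry.detect_zn_site(model)
        sig = [("zn", tuple(summaries), tuple(round(r.distance, 6) for r in recs))]
        for fn in (geometry.detect_hbonds, geometry.detect_tyr_i4_hbond, geometry.detect_cation_pi):
            out = fn(model)
            sig.append(
                tuple(
                    (r.kind, r.partners, round(r.distance, 6),
                     None if r.angle is None else round(r.angle, 5), r.seq_separation)
                    for r in out
                )
            )
    return sig


def test_detectors_invariant_under_rigid_transforms():
    """Random rotations + translations must not change any detection."""
    rng = np.random.default_rng(7)
    models = _all_feature_models()
    refs = [_feature_signature(m) for m in models]
    for _ in range(20):
        R, t = random_rigid_transform(rng)
        for m, ref in zip(models, refs):
            assert _feature_signature(transform_model(m, R, t)) == ref


def _brute_force_hbonds(model, dmax=3.5, min_sep=5):
    """Naive all-pairs re-implementation used as an oracle."""
    from pzbd.geometry import _BACKBONE, _SIDECHAIN_ACCEPTORS, _SIDECHAIN_DONORS

    found = set()
    res_list = model.residues
    ordinals = {}
    counters = {}
    for r in res_list:
        ordinals[id(r)] = counters.get(r.chain, 0)
        counters[r.chain] = ordinals[id(r)] + 1
    for r1 in res_list:
        for n1, x1 in r1.atoms.items():
            d1 = n1 == "N" or n1 in _SIDECHAIN_DONORS.get(r1.resname, ())
            if not d1:
                continue
            for r2 in res_list:
                if r1 is r2:
                    continue
                for n2, x2 in r2.atoms.items():
                    a2 = n2 == "O" or n2 in _SIDECHAIN_ACCEPTORS.get(r2.resname, ())
                    if not a2 or (n1 in _BACKBONE and n2 in _BACKBONE):
                        continue
                    if np.linalg.norm(x1 - x2) <= dmax:
                        found.add(frozenset([(r1.chain, r1.resnum, n1), (r2.chain, r2.resnum, n2)]))
    return found


def test_hbond_detector_equals_all_pairs_enumeration():
    for spec in (
        GeometrySpec(kind="hbond", distance=2.9, separation=10),
        GeometrySpec(kind="hbond", distance=3.4, separation=3),
        GeometrySpec(kind="tyr_i4_hbond", distance=2.9),
    ):
        model = read_structure(gen_structure(spec)[0])
        got = {frozenset(r.partners) for r in geometry.detect_hbonds(model)}
        assert got == _brute_force_hbonds(model)
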