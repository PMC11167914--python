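"""Geometry core: superposition, TM-score, torsion round trips, secondary
structure, accessibility and compactness."""

import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

import foldpath as fp
from foldpath import structio as st

from conftest import build_chain, ideal_helix, extended_chain, random_chain


def random_rigid(rng):
    R = Rotation.random(random_state=np.random.RandomState(
        rng.integers(2 ** 31))).as_matrix()
    t = rng.uniform(-20, 20, 3)
    return R, t


# --------------------------------------------------------------------------
# PDB I/O


def test_pdb_round_trip_preserves_coordinates(tmp_path):
    s = ideal_helix(12)
    path = tmp_path / "helix.pdb"
    st.write_structure(path, s)
    r = st.read_structure(path)
    assert r.sequence == s.sequence
    assert np.abs(r.backbone - s.backbone).max() < 1e-3  # PDB precision


def test_read_drops_residue_missing_backbone_atom(tmp_path):
    s = ideal_helix(5)
    path = tmp_path / "full.pdb"
    st.write_structure(path, s)
    lines = [ln for ln in path.read_text().splitlines()
             if not (ln.startswith("ATOM") and " O  " in ln
                     and " 3 " in ln[20:30])]
    broken = tmp_path / "broken.pdb"
    broken.write_text("\n".join(lines) + "\n")
    with pytest.warns(UserWarning):
        r = st.read_structure(broken)
    assert len(r) == 4


def test_read_empty_structure_errors(tmp_path):
    path = tmp_path / "empty.pdb"
    path.write_text("END\n")
    with pytest.raises(st.StructureError):
        st.read_structure(path)


# --------------------------------------------------------------------------
# superposition


def test_kabsch_identity():
    s = ideal_helix(10)
    sup = st.kabsch_superpose(s.ca, s.ca)
    assert sup.rmsd < 1e-9
    assert np.allclose(sup.rotation, np.eye(3), atol=1e-9)


def test_kabsch_recovers_known_rotation():
    s = ideal_helix(10)
    R = Rotation.from_euler("z", 90, degrees=True).as_matrix()
    moved = s.ca @ R.T
    sup = st.kabsch_superpose(moved, s.ca)
    assert sup.rmsd < 1e-9
    assert np.allclose(sup.rotation @ R, np.eye(3), atol=1e-9)


def test_kabsch_rejects_degenerate_input():
    with pytest.raises(st.StructureError):
        st.kabsch_superpose(np.zeros((2, 3)), np.zeros((2, 3)))


def _quaternion_rmsd_oracle(mobile, fixed):
    """Brute-force minimal RMSD over rigid transforms: numeric optimization
    on a quaternion parametrization, multiple restarts."""
    mc, fc = mobile.mean(0), fixed.mean(0)

    def loss(q):
        q = q / np.linalg.norm(q)
        R = Rotation.from_quat(q).as_matrix()
        moved = (mobile - mc) @ R.T + fc
        return np.sqrt(((moved - fixed) ** 2).sum(-1).mean())

    best = np.inf
    rs = np.random.RandomState(0)
    for _ in range(12):
        q0 = rs.normal(size=4)
        res = minimize(loss, q0, method="Nelder-Mead",
                       options={"xatol": 1e-10, "fatol": 1e-12,
                                "maxiter": 4000})
        best = min(best, res.fun)
    return best


def test_kabsch_rmsd_matches_brute_force_oracle():
    rng = np.random.default_rng(42)
    pts = rng.uniform(-5, 5, (10, 3))
    noisy = pts + rng.normal(0, 0.5, (10, 3))
    R, t = random_rigid(rng)
    sup = st.kabsch_superpose(noisy @ R.T + t, pts)
    assert sup.rmsd == pytest.approx(_quaternion_rmsd_oracle(noisy, pts),
                                     abs=1e-6)


def test_superposition_rmsd_invariant_under_rigid_motion():
    rng = np.random.default_rng(3)
    a = random_chain(15, rng)
    b = random_chain(15, rng)
    base = st.kabsch_superpose(a.ca, b.ca).rmsd
    for _ in range(3):
        R, t = random_rigid(rng)
        moved = st.kabsch_superpose(a.ca @ R.T + t, b.ca).rmsd
        assert moved == pytest.approx(base, abs=1e-6)


# --------------------------------------------------------------------------
# TM-score


def test_tm_score_self_is_one():
    s = ideal_helix(30)
    assert st.tm_score(s, s) == pytest.approx(1.0, abs=1e-9)


def test_tm_score_rigid_invariance():
    rng = np.random.default_rng(7)
    s = random_chain(30, rng)
    R, t = random_rigid(rng)
    assert st.tm_score(s.transformed(R, t), s) == pytest.approx(1.0,
                                                                abs=1e-6)


def test_tm_score_requires_three_pairs():
    s = ideal_helix(10)
    with pytest.raises(st.StructureError):
        st.tm_score(s, s, mapping=[(0, 0), (1, 1)])


def tm_oracle(mobile, fixed, l_ref):
    """Exhaustive d0-weighted scoring under a numeric superposition search
    (rotation vector + translation, many restarts)."""
    d0 = st.tm_d0(l_ref)

    def neg_tm(x):
        R = Rotation.from_rotvec(x[:3]).as_matrix()
        moved = mobile @ R.T + x[3:]
        d = np.linalg.norm(moved - fixed, axis=1)
        return -np.sum(1.0 / (1.0 + (d / d0) ** 2)) / l_ref

    best = 0.0
    rs = np.random.RandomState(1)
    starts = [np.zeros(6)]
    sup0 = st.kabsch_superpose(mobile, fixed)
    starts.append(np.concatenate([Rotation.from_matrix(
        sup0.rotation).as_rotvec(), sup0.translation]))
    for _ in range(10):
        starts.append(np.concatenate([rs.normal(0, 2, 3),
                                      rs.normal(0, 5, 3)]))
    for x0 in starts:
        res = minimize(neg_tm, x0, method="Nelder-Mead",
                       options={"maxiter": 3000, "fatol": 1e-10})
        best = max(best, -res.fun)
    return best


def test_tm_score_matches_superposition_search_oracle():
    rng = np.random.default_rng(11)
    helix = ideal_helix(30)
    noisy = helix.copy()
    noisy.backbone = noisy.backbone + rng.normal(0, 3.0 / np.sqrt(3),
                                                 noisy.backbone.shape)
    got = st.tm_score(noisy, helix)
    want = tm_oracle(noisy.ca, helix.ca, 30)
    assert got == pytest.approx(want, abs=0.01)


# --------------------------------------------------------------------------
# torsions <-> Cartesian


def test_ideal_helix_ca_spacing():
    h = ideal_helix(12)
    for i in range(3, 8):
        assert 5.0 <= np.linalg.norm(h.ca[i] - h.ca[i + 3]) <= 5.5


def test_extended_chain_is_longer_than_helix():
    h, e = ideal_helix(20), extended_chain(20)
    assert (np.linalg.norm(e.ca[5] - e.ca[7])
            > np.linalg.norm(h.ca[5] - h.ca[7]))
    assert st.radius_of_gyration(e) > st.radius_of_gyration(h)


def test_torsion_round_trip():
    rng = np.random.default_rng(5)
    L = 25
    t = st.TorsionChain(rng.uniform(-179, 179, L), rng.uniform(-179, 179, L),
                        np.full(L, 180.0), "A" * L)
    s = st.rebuild_cartesian(t)
    back = st.measure_torsions(s)
    assert np.abs(back.phi[1:] - t.phi[1:]).max() < 1e-3
    assert np.abs(back.psi - t.psi).max() < 1e-3


def test_rebuild_preserves_template_geometry():
    rng = np.random.default_rng(9)
    s = random_chain(15, rng)
    g = st.GEOMETRY_TEMPLATE
    for i in range(15):
        assert np.linalg.norm(s.backbone[i, 1] - s.backbone[i, 0]) == \
            pytest.approx(g["bond_N_CA"], abs=1e-9)
        assert np.linalg.norm(s.backbone[i, 2] - s.backbone[i, 1]) == \
            pytest.approx(g["bond_CA_C"], abs=1e-9)
    for i in range(14):
        assert np.linalg.norm(s.backbone[i + 1, 0] - s.backbone[i, 2]) == \
            pytest.approx(g["bond_C_N"], abs=1e-9)


# --------------------------------------------------------------------------
# secondary structure


def test_ideal_helix_labeled_helical():
    labels = st.assign_secondary_structure(ideal_helix(20))
    assert np.mean(labels == "H") >= 0.8


def test_extended_chain_has_no_helix():
    labels = st.assign_secondary_structure(extended_chain(20))
    assert np.mean(labels == "H") == 0.0
    assert np.mean(labels == "E") > 0.5


def test_random_coil_mostly_unstructured():
    fracs = []
    for seed in range(8):
        rng = np.random.default_rng(seed)
        s = random_chain(30, rng, compact=False)
        labels = st.assign_secondary_structure(s)
        fracs.append(np.mean(labels == "H"))
    assert np.mean(fracs) < 0.2


# --------------------------------------------------------------------------
# accessibility


def test_isolated_residue_fully_exposed():
    s = ideal_helix(1)
    assert st.relative_solvent_accessibility(s)[0] >= 0.9


def _dense_globule(n=50, spacing=4.5):
    """Synthetic dense globule: residues on lattice points inside a ball,
    with compact per-residue atom placements (not a valid chain — only the
    occlusion geometry matters for accessibility)."""
    pts = []
    r = 3
    for x in range(-r, r + 1):
        for y in range(-r, r + 1):
            for z in range(-r, r + 1):
                if x * x + y * y + z * z <= r * r:
                    pts.append((x, y, z))
    pts = np.array(sorted(pts, key=lambda p: (p[0]**2 + p[1]**2 + p[2]**2)))
    pts = pts[:n] * spacing
    L = len(pts)
    bb = np.zeros((L, 4, 3))
    bb[:, 0] = pts + [1.2, 0, 0]
    bb[:, 1] = pts
    bb[:, 2] = pts + [0, 1.2, 0]
    bb[:, 3] = pts + [0, 1.2, 1.2]
    cb = pts + [0, 0, 1.5]
    return st.ProteinStructure("globule", "A" * L, bb, cb)


def test_core_of_compact_globule_is_buried():
    s = _dense_globule()
    rsa = st.relative_solvent_accessibility(s)
    central = int(np.argmin(np.linalg.norm(s.ca - s.ca.mean(0), axis=1)))
    assert rsa[central] < 0.25


def test_buried_fraction_decreases_on_expansion():
    best = min((random_chain(40, np.random.default_rng(k))
                for k in range(10)), key=st.radius_of_gyration)
    fractions = []
    for scale in (1.0, 1.5, 2.5):
        s = best.copy()
        centroid = s.ca.mean(0)
        s.backbone = (s.backbone - centroid) * scale + centroid
        s.cb = (s.cb - centroid) * scale + centroid
        rsa = st.relative_solvent_accessibility(s)
        fractions.append(np.mean(rsa < 0.25))
    assert fractions[0] >= fractions[1] >= fractions[2]


def _asa_oracle(s):
    """Independent brute-force sphere-dot ASA (plain loops, no tree)."""
    coords, res_idx, names = s.all_atoms()
    radii = np.array([st._ASA_RADII[n] for n in names]) + st._ASA_PROBE
    n = 92
    golden = np.pi * (1 + np.sqrt(5))
    dots = []
    for k in range(n):
        z = 1 - 2 * (k + 0.5) / n
        r = np.sqrt(max(0.0, 1 - z * z))
        th = golden * (k + 0.5)
        dots.append((r * np.cos(th), r * np.sin(th), z))
    dots = np.array(dots)
    rsa = np.zeros(len(s))
    for a in range(len(coords)):
        exposed = 0
        for d in dots:
            p = coords[a] + radii[a] * d
            ok = True
            for b in range(len(coords)):
                if b == a:
                    continue
                if np.linalg.norm(p - coords[b]) < radii[b]:
                    ok = False
                    break
            if ok:
                exposed += 1
        asa = 4 * np.pi * radii[a] ** 2 * exposed / n
        rsa[res_idx[a]] += asa
    for i in range(len(s)):
        rsa[i] /= st.MAX_ASA.get(s.sequence[i], 200.0)
    return np.clip(rsa, 0, 1.2)


def test_rsa_and_rg_match_independent_reimplementation():
    for seed in range(3):
        s = random_chain(12, np.random.default_rng(seed))
        got = st.relative_solvent_accessibility(s)
        want = _asa_oracle(s)
        assert np.abs(got - want).max() <= 0.02 * max(1.0, want.max())
        ca = s.ca
        rg_oracle = np.sqrt(np.mean([np.sum((c - ca.mean(0)) ** 2)
                                     for c in ca]))
        assert st.radius_of_gyration(s) == pytest.approx(rg_oracle,
                                                         abs=1e-9)


# --------------------------------------------------------------------------
# radius of gyration closed forms


def test_rg_closed_forms():
    s = ideal_helix(2)
    s.backbone[:, 1] = [[0, 0, 0], [2, 0, 0]]
    assert st.radius_of_gyration(s) == pytest.approx(1.0, abs=1e-12)
    s.backbone[:, 1] = [[1, 1, 1], [1, 1, 1]]
    assert st.radius_of_gyration(s) == pytest.approx(0.0, abs=1e-12)
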