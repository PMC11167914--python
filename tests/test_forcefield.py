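"""Force-field terms: hand-computed values, qualitative geometry checks,
invariances and decoy discrimination."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

import foldpath as fp
from foldpath import forcefield as ff
from foldpath.structio import ProteinStructure, TorsionChain, \
    rebuild_cartesian, measure_torsions

from conftest import ideal_helix, extended_chain, random_chain


def two_parallel_strands(gap=4.8, n=6, spacer=2, sequence=None):
    """Two parallel extended strands ``gap`` Angstrom apart, joined by a
    geometrically meaningless spacer (only the strand geometry matters)."""
    s1 = extended_chain(n)
    L = 2 * n + spacer
    if sequence is None:
        sequence = "A" * L
    bb = np.full((L, 4, 3), 500.0)
    cb = np.full((L, 3), 500.0)
    bb[:n] = s1.backbone
    cb[:n] = s1.cb
    offset = np.array([0.0, gap, 0.0])
    bb[n + spacer:] = s1.backbone + offset
    cb[n + spacer:] = s1.cb + offset
    # spacer residues parked far away so they do not interact; slight
    # per-atom offsets keep torsion measurement non-degenerate
    for k in range(spacer):
        bb[n + k] += np.array([1000.0 + 50.0 * k, 0, 0])
        bb[n + k] += np.arange(4)[:, None] * np.array([1.5, 1.0, 0.5])
        cb[n + k] += np.array([1000.0 + 50.0 * k, 0, 0])
    return ProteinStructure("strands", sequence, bb, cb)


# --------------------------------------------------------------------------
# vdw


def test_vdw_extended_chain_is_zero():
    assert ff.vdw_term(extended_chain(20)) == 0.0


def _cb_pair_structure(d):
    """Three residues: everything far apart except CB(0) and CB(2) at
    distance d."""
    L = 3
    bb = np.zeros((L, 4, 3))
    for i in range(L):
        bb[i] = 200.0 * (i + 1)
    cb = np.array([[0.0, 0, 0], [400.0, 0, 0], [d, 0.0, 0.0]])
    bb[0] += np.array([-50.0, 0, 0])
    bb[2] += np.array([50.0, 0, 0])
    return ProteinStructure("pair", "AAA", bb, cb)


def test_vdw_boundary_contact_is_zero():
    r = 2 * 1.65  # CB-CB repulsion radius sum
    assert ff.vdw_term(_cb_pair_structure(r)) == pytest.approx(0.0,
                                                               abs=1e-12)


def test_vdw_half_radius_hand_value():
    r = 2 * 1.65
    got = ff.vdw_term(_cb_pair_structure(r / 2))
    assert got == pytest.approx(0.5625, abs=1e-9)


# --------------------------------------------------------------------------
# hydrogen bonding


def test_hb_helix_strictly_negative_vs_extended():
    h = ff.hb_srbb_term(ideal_helix(20))
    e = ff.hb_srbb_term(extended_chain(20))
    assert h < -1.0
    assert e == pytest.approx(0.0, abs=1e-6)


def test_hb_short_chain_is_zero():
    assert ff.hb_srbb_term(extended_chain(4)) == pytest.approx(0.0,
                                                               abs=1e-9)


def test_energy_terms_rigid_motion_invariant():
    rng = np.random.default_rng(1)
    s = random_chain(25, rng)
    R = Rotation.from_euler("xyz", [1.0, -0.5, 2.0]).as_matrix()
    moved = s.transformed(R, np.array([7.0, -3.0, 11.0]))
    for term in (ff.vdw_term, ff.hb_srbb_term, ff.pair_term, ff.env_term,
                 ff.cbeta_term):
        assert term(moved) == pytest.approx(term(s), abs=1e-9)
    e1 = ff.physical_energy(s, 2)
    e2 = ff.physical_energy(moved, 2)
    assert e2.total == pytest.approx(e1.total, abs=1e-9)


# --------------------------------------------------------------------------
# stage-2 knowledge terms


def test_pair_term_salt_bridge():
    seq = list("A" * 14)
    seq[0], seq[8] = "D", "K"
    s = two_parallel_strands(gap=4.8, sequence="".join(seq))
    assert ff.pair_term(s) == pytest.approx(-1.0)


def test_pair_term_like_charges_penalized():
    seq = list("A" * 14)
    seq[0], seq[8] = "K", "R"
    s = two_parallel_strands(gap=4.8, sequence="".join(seq))
    assert ff.pair_term(s) == pytest.approx(0.5)


def test_pair_term_disulfide():
    seq = list("A" * 14)
    seq[0], seq[8] = "C", "C"
    s = two_parallel_strands(gap=4.0, sequence="".join(seq))
    assert ff.pair_term(s) == pytest.approx(-2.0)


def test_sheet_and_rsigma_reward_paired_strands():
    paired = two_parallel_strands(gap=4.8)
    apart = two_parallel_strands(gap=12.0)
    assert ff.sheet_term(paired) < 0
    assert ff.rsigma_term(paired) < 0
    assert ff.sheet_term(apart) == 0.0
    assert ff.rsigma_term(apart) == 0.0


def test_cbeta_rewards_compactness():
    ext = extended_chain(40)
    compact = min((random_chain(40, np.random.default_rng(k))
                   for k in range(10)), key=fp.radius_of_gyration)
    assert ff.cbeta_term(compact) < ff.cbeta_term(ext)


def test_env_buries_hydrophobics():
    """A hydrophobic-core sequence scores lower (better) than the same
    geometry with polar residues in the core."""
    compact = min((random_chain(40, np.random.default_rng(k))
                   for k in range(10)), key=fp.radius_of_gyration)
    n = ff._neighbor_counts(compact)
    order = np.argsort(-n)
    seq_hydro = np.array(list("N" * 40))
    seq_hydro[order[:15]] = "I"          # hydrophobics inside
    hydro = compact.copy()
    hydro.sequence = "".join(seq_hydro)
    seq_polar = np.array(list("I" * 40))
    seq_polar[order[:15]] = "N"          # polars inside
    polar = compact.copy()
    polar.sequence = "".join(seq_polar)
    assert ff.env_term(hydro) < ff.env_term(polar)


# --------------------------------------------------------------------------
# combined potentials


def test_stage1_combines_only_two_terms():
    s = ideal_helix(15)
    w = fp.EnergyWeights()
    e = ff.physical_energy(s, 1, w)
    assert set(e.terms) == {"vdw", "hb_srbb"}
    assert e.total == pytest.approx(
        w.stage1["vdw"] * e.terms["vdw"]
        + w.stage1["hb_srbb"] * e.terms["hb_srbb"], abs=1e-12)


def test_weights_linearity():
    s = ideal_helix(15)
    w = fp.EnergyWeights()
    base = ff.physical_energy(s, 2, w).total
    w2 = fp.EnergyWeights(
        stage1={k: 2 * v for k, v in w.stage1.items()},
        stage2={k: 2 * v for k, v in w.stage2.items()})
    assert ff.physical_energy(s, 2, w2).total == pytest.approx(2 * base,
                                                               abs=1e-9)


def test_unknown_stage_errors():
    with pytest.raises(ValueError):
        ff.physical_energy(ideal_helix(10), 3)


def test_native_beats_shuffled_decoys():
    """The native toy fold ranks in the top 10% of 100 shuffled-torsion
    decoys by stage-2 total energy."""
    native = fp.make_native(fp.BLUEPRINTS["mixed"], seed=1)
    t = measure_torsions(native)
    base = np.stack([t.phi, t.psi, t.omega], axis=1)
    base[np.isnan(base[:, 0]), 0] = -139.0
    base[np.isnan(base[:, 2]), 2] = 180.0
    e_native = ff.physical_energy(native, 2).total
    wins = 0
    rng = np.random.default_rng(0)
    n_decoys = 100
    worse = 0
    for _ in range(n_decoys):
        perm = rng.permutation(len(native))
        tor = base[perm]
        decoy = rebuild_cartesian(
            TorsionChain(tor[:, 0], tor[:, 1], tor[:, 2]),
            native.sequence)
        if ff.physical_energy(decoy, 2).total > e_native:
            worse += 1
    assert worse >= 0.9 * n_decoys


# --------------------------------------------------------------------------
# statistical potential


def _restraints_for(target, f_values=None):
    L = len(target)
    f = fp.FValueProfile(np.full(L, 1.0) if f_values is None
                         else np.asarray(f_values), 1)
    return fp.restraint_map(target, f)


def test_statistical_energy_zero_at_target():
    s = ideal_helix(20)
    rm = _restraints_for(s)
    assert ff.statistical_energy(s, rm) == 0.0
    assert ff.statistical_energy(s, rm, weighted=False) == 0.0


def test_statistical_energy_single_pair_hand_value():
    """Single pair at |i-j| = 10: target distance 10, conformation
    distance 8, w = 0.5 -> 0.5 * 2 / ln(10.001)."""
    L = 11
    d = np.zeros((L, L))
    d[0, 10] = d[10, 0] = 10.0
    idx = np.arange(L)
    dstar = np.log(1e-3 + np.abs(idx[:, None] - idx[None, :]))
    w = np.full((L, L), 0.5)
    mask = np.zeros((L, L), dtype=bool)
    mask[0, 10] = True
    rm = fp.RestraintMap(d, dstar, w, 1e-3, 2, mask)
    conf = ideal_helix(L)
    conf.backbone[:, 1] = 0.0
    conf.backbone[10, 1] = [8.0, 0.0, 0.0]
    got = ff.statistical_energy(conf, rm)
    assert got == pytest.approx(0.5 * 2.0 / np.log(10.001), abs=1e-9)
    unweighted = ff.statistical_energy(conf, rm, weighted=False)
    assert unweighted == pytest.approx(2.0 / np.log(10.001), abs=1e-9)


def test_statistical_energy_scaling_increases():
    s = ideal_helix(20)
    rm = _restraints_for(s)
    scaled = s.copy()
    scaled.backbone = scaled.backbone * 1.5
    scaled.cb = scaled.cb * 1.5
    assert ff.statistical_energy(scaled, rm) > 0


def test_weighted_not_above_unweighted():
    rng = np.random.default_rng(4)
    target = ideal_helix(25)
    rm = _restraints_for(target, rng.uniform(0, 1, 25))
    conf = random_chain(25, rng)
    assert (ff.statistical_energy(conf, rm)
            <= ff.statistical_energy(conf, rm, weighted=False))


def test_statistical_energy_nonincreasing_toward_target():
    """Linearly interpolating distances toward the target map never
    increases the restraint energy (per-pair convexity of |.|)."""
    rng = np.random.default_rng(8)
    target = ideal_helix(20)
    rm = _restraints_for(target)
    conf = random_chain(20, rng)
    from scipy.spatial.distance import pdist, squareform
    d_conf = squareform(pdist(conf.ca))
    m = rm.mask
    energies = []
    for alpha in np.linspace(0, 1, 6):
        d_mix = (1 - alpha) * d_conf + alpha * rm.d
        e = float((np.abs(rm.d[m] - d_mix[m]) / rm.dstar[m]
                   * rm.w[m]).sum())
        energies.append(e)
    assert all(a >= b - 1e-9 for a, b in zip(energies, energies[1:]))


def test_length_mismatch_errors():
    rm = _restraints_for(ideal_helix(20))
    with pytest.raises(ValueError):
        ff.statistical_energy(ideal_helix(10), rm)


def test_weights_loaded_from_toml(tmp_path):
    cfg = tmp_path / "weights.toml"
    cfg.write_text("kT_stati = 1.5\n\n[stage2]\nenv = 3.0\n")
    w = fp.EnergyWeights.from_toml(cfg)
    assert w.kT_stati == 1.5
    assert w.stage2["env"] == 3.0
    assert w.stage2["vdw"] == 2.0   # untouched defaults remain
    assert w.kT_physi == 5.0
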