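"""Stage-specific folding force field.

Two potentials drive the sampler:

* a *physical* potential at centroid (backbone + CB) resolution.  Stage 1
  uses only steric repulsion (vdw) and short-range backbone hydrogen
  bonding (hb_srbb), enough to let individual helices and adjacent hairpins
  form.  Stage 2 adds six knowledge-inspired terms — pair (electrostatics /
  disulfide), env (hydrophobic burial), cbeta (compaction), sheet (strand
  pairing), hs_pair (helix–strand packing) and rsigma (strand register) —
  in the spirit of classic centroid scoring functions, but with simple
  analytic forms so the package is self-contained and every term testable.

* a *statistical* potential: a restraint sum |d_model - d_conf| / d* over
  residue pairs, weighted by the conservation pair weights during the
  nucleation stage and unweighted during finalization.

All terms depend only on internal distances and angles, hence are invariant
under rigid motion of the conformation.  The default term weights are
uniform (1.0) except a doubled vdw weight so hard clashes dominate; they
are package defaults, not values from any external parameter table, and are
overridable via a TOML file.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .structio import ProteinStructure, assign_secondary_structure
from .foldinfo import RestraintMap

__all__ = [
    "EnergyWeights",
    "EnergyBreakdown",
    "physical_energy",
    "statistical_energy",
    "STAGE1_TERMS",
    "STAGE2_TERMS",
]

STAGE1_TERMS = ("vdw", "hb_srbb")
STAGE2_TERMS = ("vdw", "hb_srbb", "pair", "env", "sheet", "hs_pair",
                "cbeta", "rsigma")

# repulsion-only radii per reduced-atom type (A); deliberately below
# van-der-Waals contact so native hydrogen-bond distances do not clash
_REPULSION_RADII = {"N": 1.35, "CA": 1.55, "C": 1.50, "O": 1.25, "CB": 1.65}

# Kyte–Doolittle hydropathy, rescaled to [-1, 1]
_KD = {
    "I": 4.5, "V": 4.2, "L": 3.8, "F": 2.8, "C": 2.5, "M": 1.9, "A": 1.8,
    "G": -0.4, "T": -0.7, "S": -0.8, "W": -0.9, "Y": -1.3, "P": -1.6,
    "H": -3.2, "E": -3.5, "Q": -3.5, "D": -3.5, "N": -3.5, "K": -3.9,
    "R": -4.5,
}

_NEGATIVE = set("DE")
_POSITIVE = set("KR")

_ENV_NBAR = 8.0       # reference CB neighbor count within 10 A
_CBETA_CAP = 10.0     # neighbor-count saturation for the compaction term
_HB_D0 = 2.9          # O..N optimum (A)
_HB_DCUT = 3.5        # O..N zero crossing (A)
_SHEET_DMIN, _SHEET_DMAX = 4.2, 5.5   # cross-strand CA pairing window (A)
_RSIGMA_D0 = 4.8      # optimal inter-strand distance (A)


@dataclass
class EnergyWeights:
    """Per-term weights for both stages plus the two Metropolis
    temperatures.  kT_physi deliberately exceeds kT_stati: the physical
    potential gates physical plausibility, it need not decrease
    monotonically, while the statistical potential drives folding."""

    stage1: dict = field(default_factory=lambda: {
        "vdw": 2.0, "hb_srbb": 1.0})
    stage2: dict = field(default_factory=lambda: {
        "vdw": 2.0, "hb_srbb": 1.0, "pair": 1.0, "env": 1.0,
        "sheet": 1.0, "hs_pair": 1.0, "cbeta": 1.0, "rsigma": 1.0})
    kT_physi: float = 5.0
    kT_stati: float = 2.0

    def for_stage(self, stage: int) -> dict:
        if stage == 1:
            return self.stage1
        if stage == 2:
            return self.stage2
        raise ValueError(f"unknown stage {stage}")

    @classmethod
    def from_toml(cls, path):
        import tomllib
        with open(path, "rb") as fh:
            data = tomllib.load(fh)
        w = cls()
        w.stage1.update(data.get("stage1", {}))
        w.stage2.update(data.get("stage2", {}))
        w.kT_physi = float(data.get("kT_physi", w.kT_physi))
        w.kT_stati = float(data.get("kT_stati", w.kT_stati))
        return w


@dataclass
class EnergyBreakdown:
    terms: dict
    total: float
    stage: int

    @classmethod
    def combine(cls, terms: dict, weights: dict, stage: int):
        total = float(sum(weights[k] * terms[k] for k in terms))
        return cls(dict(terms), total, stage)


# --------------------------------------------------------------------------
# individual physical terms


def vdw_term(conf: ProteinStructure) -> float:
    """Purely repulsive steric clash score over backbone + CB atoms.

    Pairs at residue separation >= 2 closer than the sum of repulsion
    radii r contribute ((r^2 - d^2) / r^2)^2; zero otherwise.
    """
    coords, res_idx, names = conf.all_atoms()
    radii = np.array([_REPULSION_RADII[n] for n in names])
    d = squareform(pdist(coords))
    r = radii[:, None] + radii[None, :]
    sep = np.abs(res_idx[:, None] - res_idx[None, :])
    iu = np.triu_indices(len(coords), k=1)
    mask = (sep[iu] >= 2) & (d[iu] < r[iu])
    if not mask.any():
        return 0.0
    dd, rr = d[iu][mask], r[iu][mask]
    return float((((rr ** 2 - dd ** 2) / rr ** 2) ** 2).sum())


def hb_srbb_term(conf: ProteinStructure) -> float:
    """Short-range backbone-backbone hydrogen bonding (always <= 0).

    For residue pairs at separation 3..5, a smooth distance well centered
    at 2.9 A on the O(i)..N(j) distance (zero beyond 3.5 A) times an
    angular factor penalizing non-linear C=O..N geometry.
    """
    L = len(conf)
    if L < 4:
        return 0.0
    O = conf.backbone[:, 3]
    N = conf.backbone[:, 0]
    C = conf.backbone[:, 2]
    total = 0.0
    for s in (3, 4, 5):
        if L <= s:
            continue
        d = np.linalg.norm(O[:-s] - N[s:], axis=1)
        near = d < _HB_DCUT
        if not near.any():
            continue
        f = np.clip(1.0 - ((d[near] - _HB_D0) / (_HB_DCUT - _HB_D0)) ** 2,
                    0.0, None)
        co = O[:-s][near] - C[:-s][near]
        co /= np.linalg.norm(co, axis=1, keepdims=True)
        on = N[s:][near] - O[:-s][near]
        on /= np.linalg.norm(on, axis=1, keepdims=True)
        g = np.clip((co * on).sum(1), 0.0, None) ** 2
        total -= float((f * g).sum())
    return total


def _cb_distance_matrix(conf):
    return squareform(pdist(conf.cb))


def _neighbor_counts(conf, cb_d=None, cutoff=10.0):
    if cb_d is None:
        cb_d = _cb_distance_matrix(conf)
    n = (cb_d < cutoff).sum(1) - 1
    return n.astype(float)


def pair_term(conf: ProteinStructure, cb_d=None) -> float:
    """Residue-pair electrostatics and disulfides at CB resolution.

    CB pairs below 6 A with sequence separation >= 4: -1 per
    opposite-charge pair, +0.5 per like-charge pair, -2 per Cys-Cys pair
    below 4.5 A."""
    if cb_d is None:
        cb_d = _cb_distance_matrix(conf)
    L = len(conf)
    seq = conf.sequence
    total = 0.0
    for i in range(L):
        for j in range(i + 4, L):
            d = cb_d[i, j]
            if d >= 6.0:
                continue
            a, b = seq[i], seq[j]
            if a == "C" and b == "C" and d < 4.5:
                total -= 2.0
            elif ((a in _NEGATIVE and b in _POSITIVE)
                    or (a in _POSITIVE and b in _NEGATIVE)):
                total -= 1.0
            elif ((a in _NEGATIVE and b in _NEGATIVE)
                    or (a in _POSITIVE and b in _POSITIVE)):
                total += 0.5
    return total


def env_term(conf: ProteinStructure, cb_d=None) -> float:
    """Hydrophobic burial: hydrophobic residues are rewarded (negative)
    when their CB neighbor count exceeds the reference count, polar
    residues when exposed."""
    n = _neighbor_counts(conf, cb_d)
    h = np.array([-_KD.get(a, 0.0) / 4.5 for a in conf.sequence])
    return float((h * (n - _ENV_NBAR) / _ENV_NBAR).sum())


def cbeta_term(conf: ProteinStructure, cb_d=None) -> float:
    """Saturating compaction reward: -mean(min(n_i, cap))."""
    n = _neighbor_counts(conf, cb_d)
    return float(-np.minimum(n, _CBETA_CAP).sum() / len(conf))


def _segments(labels, kind):
    segs = []
    i = 0
    L = len(labels)
    while i < L:
        if labels[i] == kind:
            j = i
            while j < L and labels[j] == kind:
                j += 1
            segs.append((i, j))
            i = j
        else:
            i += 1
    return segs


def _strand_pairings(conf, labels):
    """Qualifying strand-segment pairs with their close CA cross-pairs."""
    ca = conf.ca
    strands = _segments(labels, "E")
    pairings = []
    for a in range(len(strands)):
        for b in range(a + 1, len(strands)):
            s1, s2 = strands[a], strands[b]
            i_idx = np.arange(*s1)
            j_idx = np.arange(*s2)
            d = np.linalg.norm(ca[i_idx][:, None, :] - ca[j_idx][None, :, :],
                               axis=2)
            close = np.argwhere((d >= _SHEET_DMIN) & (d <= _SHEET_DMAX))
            if len(close) >= 2:
                pairs = np.stack([i_idx[close[:, 0]], j_idx[close[:, 1]]],
                                 axis=1)
                dists = d[close[:, 0], close[:, 1]]
                pairings.append((s1, s2, pairs, dists))
    return pairings


def sheet_term(conf: ProteinStructure, labels=None, pairings=None) -> float:
    """-1 per strand-segment pair with >= 2 cross-strand CA contacts in
    the 4.2–5.5 A pairing window."""
    if pairings is None:
        if labels is None:
            labels = assign_secondary_structure(conf)
        pairings = _strand_pairings(conf, labels)
    return float(-len(pairings))


def rsigma_term(conf: ProteinStructure, labels=None, pairings=None) -> float:
    """Strand-pair geometry: a distance well around 4.8 A combined with a
    register-offset penalty (0.25 per residue of register spread, parallel
    or antiparallel, whichever fits better)."""
    if pairings is None:
        if labels is None:
            labels = assign_secondary_structure(conf)
        pairings = _strand_pairings(conf, labels)
    total = 0.0
    for _s1, _s2, pairs, dists in pairings:
        dmean = float(dists.mean())
        off_par = pairs[:, 1] - pairs[:, 0]
        off_anti = pairs[:, 1] + pairs[:, 0]
        shift = min(np.ptp(off_par), np.ptp(off_anti))
        well = np.exp(-((dmean - _RSIGMA_D0) / 1.0) ** 2)
        total -= well * max(0.0, 1.0 - 0.25 * shift)
    return float(total)


def hs_pair_term(conf: ProteinStructure, labels=None) -> float:
    """-0.5 per helix/strand segment pair whose CA midpoints lie within
    10 A (helix packing against sheet)."""
    if labels is None:
        labels = assign_secondary_structure(conf)
    ca = conf.ca
    helices = _segments(labels, "H")
    strands = _segments(labels, "E")
    total = 0.0
    for h0, h1 in helices:
        mh = ca[h0:h1].mean(0)
        for s0, s1 in strands:
            ms = ca[s0:s1].mean(0)
            if np.linalg.norm(mh - ms) < 10.0:
                total -= 0.5
    return float(total)


# --------------------------------------------------------------------------
# combined potentials


def physical_energy(conf: ProteinStructure, stage: int,
                    weights: EnergyWeights = None) -> EnergyBreakdown:
    """Weighted physical potential for the given stage (1 or 2)."""
    if weights is None:
        weights = EnergyWeights()
    if stage not in (1, 2):
        raise ValueError(f"unknown stage {stage}")
    terms = {"vdw": vdw_term(conf), "hb_srbb": hb_srbb_term(conf)}
    if stage == 2:
        cb_d = _cb_distance_matrix(conf)
        labels = assign_secondary_structure(conf)
        pairings = _strand_pairings(conf, labels)
        terms.update({
            "pair": pair_term(conf, cb_d),
            "env": env_term(conf, cb_d),
            "sheet": sheet_term(conf, pairings=pairings),
            "hs_pair": hs_pair_term(conf, labels),
            "cbeta": cbeta_term(conf, cb_d),
            "rsigma": rsigma_term(conf, pairings=pairings),
        })
    return EnergyBreakdown.combine(terms, weights.for_stage(stage), stage)


def statistical_energy(conf: ProteinStructure, restraints: RestraintMap,
                       weighted: bool = True) -> float:
    """Restraint sum over pairs i < j with |i-j| >= min_separation:
    (w_ij or 1) * |d_target - d_conf| / d*.  Zero iff every included
    conformation distance matches the target map exactly."""
    if len(conf) != len(restraints):
        raise ValueError("conformation length does not match restraint map")
    d_conf = squareform(pdist(conf.ca))
    m = restraints.mask
    dev = np.abs(restraints.d[m] - d_conf[m]) / restraints.dstar[m]
    if weighted:
        dev = restraints.w[m] * dev
    return float(dev.sum())
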