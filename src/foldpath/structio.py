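"""Structure I/O, internal-coordinate model and core geometry.

Everything downstream speaks one geometric currency: a reduced backbone
representation (N, CA, C, O plus a CB side-chain proxy) with the chain's
conformation expressed either in Cartesian coordinates or as backbone
torsion angles (phi, psi, omega).  Fragment-assembly moves operate purely in
torsion space, so covalent geometry (bond lengths and angles) is fixed to an
ideal template and is bit-identical in every conformation the sampler ever
visits.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ProteinStructure",
    "TorsionChain",
    "SuperpositionResult",
    "GEOMETRY_TEMPLATE",
    "read_structure",
    "write_structure",
    "kabsch_superpose",
    "tm_superpose",
    "tm_score",
    "tm_d0",
    "measure_torsions",
    "rebuild_cartesian",
    "assign_secondary_structure",
    "relative_solvent_accessibility",
    "radius_of_gyration",
    "pseudo_cb",
]

# --------------------------------------------------------------------------
# constants

BACKBONE_ATOMS = ("N", "CA", "C", "O")

AA_3TO1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
AA_1TO3 = {v: k for k, v in AA_3TO1.items()}

# Ideal backbone covalent geometry (Engh–Huber-style values).  Fixed for the
# whole package so that torsion angles are the only degrees of freedom.
GEOMETRY_TEMPLATE = {
    "bond_N_CA": 1.458,
    "bond_CA_C": 1.525,
    "bond_C_N": 1.329,
    "bond_C_O": 1.231,
    "angle_N_CA_C": 111.2,
    "angle_CA_C_N": 116.2,
    "angle_C_N_CA": 121.7,
    "angle_CA_C_O": 120.8,
}

# Theoretical residue-specific maximum accessible surface areas (A^2),
# Tien et al. style values, used to turn absolute ASA into relative RSA.
MAX_ASA = {
    "A": 129.0, "R": 274.0, "N": 195.0, "D": 193.0, "C": 167.0,
    "Q": 225.0, "E": 223.0, "G": 104.0, "H": 224.0, "I": 197.0,
    "L": 201.0, "K": 236.0, "M": 224.0, "F": 240.0, "P": 159.0,
    "S": 155.0, "T": 172.0, "W": 285.0, "Y": 263.0, "V": 174.0,
}

# van-der-Waals radii used by the sphere-dot accessibility proxy
_ASA_RADII = {"N": 1.55, "CA": 1.70, "C": 1.70, "O": 1.52, "CB": 1.80}
_ASA_PROBE = 1.4
_ASA_N_DOTS = 92


class StructureError(ValueError):
    """Raised for unreadable, empty or degenerate structural input."""


# --------------------------------------------------------------------------
# domain types


@dataclass
class ProteinStructure:
    """Reduced-backbone protein chain.

    Attributes
    ----------
    id : str
        Chain identifier.
    sequence : str
        One-letter amino-acid sequence of length L.
    backbone : (L, 4, 3) float array
        Coordinates of N, CA, C, O per residue, in Angstrom.
    cb : (L, 3) float array
        CB coordinate per residue; a pseudo-CB built from N/CA/C for
        glycine (and for any rebuilt chain).
    resseq : (L,) int array
        Author residue numbering (1-based in files).
    """

    id: str
    sequence: str
    backbone: np.ndarray
    cb: np.ndarray
    resseq: np.ndarray = field(default=None)

    def __post_init__(self):
        self.backbone = np.asarray(self.backbone, dtype=float)
        self.cb = np.asarray(self.cb, dtype=float)
        L = len(self.sequence)
        if self.backbone.shape != (L, 4, 3):
            raise StructureError(
                f"backbone shape {self.backbone.shape} != ({L}, 4, 3)")
        if self.cb.shape != (L, 3):
            raise StructureError(f"cb shape {self.cb.shape} != ({L}, 3)")
        if self.resseq is None:
            self.resseq = np.arange(1, L + 1)
        self.resseq = np.asarray(self.resseq, dtype=int)

    def __len__(self):
        return len(self.sequence)

    @property
    def ca(self) -> np.ndarray:
        return self.backbone[:, 1]

    def all_atoms(self):
        """Flattened (5L, 3) coordinates plus residue-index and name arrays."""
        L = len(self)
        coords = np.concatenate(
            [self.backbone.reshape(L * 4, 3),
             self.cb.reshape(L, 3)])
        res_idx = np.concatenate(
            [np.repeat(np.arange(L), 4), np.arange(L)])
        names = np.concatenate(
            [np.tile(np.array(BACKBONE_ATOMS), L), np.full(L, "CB")])
        return coords, res_idx, names

    def transformed(self, rotation: np.ndarray, translation: np.ndarray):
        """Return a copy with ``x -> x @ rotation.T + translation`` applied."""
        bb = self.backbone @ rotation.T + translation
        cb = self.cb @ rotation.T + translation
        return ProteinStructure(self.id, self.sequence, bb, cb,
                                self.resseq.copy())

    def copy(self):
        return ProteinStructure(self.id, self.sequence, self.backbone.copy(),
                                self.cb.copy(), self.resseq.copy())


@dataclass
class TorsionChain:
    """Backbone torsions in degrees; NaN marks chain-terminal undefined angles.

    ``phi[0]`` and ``omega[0]`` have no defining atoms and are NaN.  ``psi``
    is defined for every residue because the carbonyl oxygen is placed anti
    to the next amide nitrogen, so psi can be measured from O even at the
    C-terminus.
    """

    phi: np.ndarray
    psi: np.ndarray
    omega: np.ndarray
    sequence: str = None

    def __post_init__(self):
        self.phi = np.asarray(self.phi, dtype=float)
        self.psi = np.asarray(self.psi, dtype=float)
        self.omega = np.asarray(self.omega, dtype=float)
        if not (len(self.phi) == len(self.psi) == len(self.omega)):
            raise ValueError("phi/psi/omega length mismatch")

    def __len__(self):
        return len(self.phi)

    def copy(self):
        return TorsionChain(self.phi.copy(), self.psi.copy(),
                            self.omega.copy(), self.sequence)


@dataclass
class SuperpositionResult:
    rotation: np.ndarray       # 3x3 proper orthonormal
    translation: np.ndarray    # 3-vector, Angstrom
    rmsd: float
    tm_score: float = None

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


# --------------------------------------------------------------------------
# basic vector helpers


def _dihedral(p0, p1, p2, p3):
    """Signed dihedral angle in degrees for four points (vectorized)."""
    b0 = np.asarray(p0) - np.asarray(p1)
    b1 = np.asarray(p2) - np.asarray(p1)
    b2 = np.asarray(p3) - np.asarray(p2)
    b1n = b1 / np.linalg.norm(b1, axis=-1, keepdims=True)
    v = b0 - np.sum(b0 * b1n, axis=-1, keepdims=True) * b1n
    w = b2 - np.sum(b2 * b1n, axis=-1, keepdims=True) * b1n
    x = np.sum(v * w, axis=-1)
    y = np.sum(np.cross(b1n, v) * w, axis=-1)
    return np.degrees(np.arctan2(y, x))


def pseudo_cb(n: np.ndarray, ca: np.ndarray, c: np.ndarray) -> np.ndarray:
    """Ideal tetrahedral CB from backbone N/CA/C (vectorized over residues)."""
    b = ca - n
    cc = c - ca
    a = np.cross(b, cc)
    return -0.58273431 * a + 0.56802827 * b - 0.54067466 * cc + ca


def _nerf_chain_py(phi, psi, omega, g):
    """Sequential NeRF chain build; ``g`` is the 8-vector of template
    bonds/angles.  Kept njit-compatible (scalar math only) — compiled with
    numba when available, the pure-Python path is the fallback."""
    (b_nca, b_cac, b_cn, b_co, a_ncac, a_cacn, a_cnca, a_caco) = g
    L = len(phi)
    bb = np.empty((L, 4, 3))
    deg = np.pi / 180.0
    ang0 = a_ncac * deg
    bb[0, 0, 0] = 0.0; bb[0, 0, 1] = 0.0; bb[0, 0, 2] = 0.0
    bb[0, 1, 0] = b_nca; bb[0, 1, 1] = 0.0; bb[0, 1, 2] = 0.0
    bb[0, 2, 0] = b_nca - b_cac * np.cos(ang0)
    bb[0, 2, 1] = b_cac * np.sin(ang0)
    bb[0, 2, 2] = 0.0

    def place(a, b, c, bond, angle_deg, torsion_deg, out):
        angle = angle_deg * deg
        torsion = torsion_deg * deg
        bcx = c[0] - b[0]; bcy = c[1] - b[1]; bcz = c[2] - b[2]
        norm = np.sqrt(bcx * bcx + bcy * bcy + bcz * bcz)
        bcx /= norm; bcy /= norm; bcz /= norm
        abx = b[0] - a[0]; aby = b[1] - a[1]; abz = b[2] - a[2]
        nx = aby * bcz - abz * bcy
        ny = abz * bcx - abx * bcz
        nz = abx * bcy - aby * bcx
        norm = np.sqrt(nx * nx + ny * ny + nz * nz)
        nx /= norm; ny /= norm; nz /= norm
        mx = ny * bcz - nz * bcy
        my = nz * bcx - nx * bcz
        mz = nx * bcy - ny * bcx
        d0 = -bond * np.cos(angle)
        d1 = bond * np.cos(torsion) * np.sin(angle)
        d2 = bond * np.sin(torsion) * np.sin(angle)
        out[0] = c[0] + d0 * bcx + d1 * mx + d2 * nx
        out[1] = c[1] + d0 * bcy + d1 * my + d2 * ny
        out[2] = c[2] + d0 * bcz + d1 * mz + d2 * nz

    for i in range(L):
        psi_i = psi[i]
        if np.isnan(psi_i):
            psi_i = 135.0
        if i + 1 < L:
            place(bb[i, 0], bb[i, 1], bb[i, 2], b_cn, a_cacn, psi_i,
                  bb[i + 1, 0])
            om = omega[i + 1]
            if np.isnan(om):
                om = 180.0
            place(bb[i, 1], bb[i, 2], bb[i + 1, 0], b_nca, a_cnca, om,
                  bb[i + 1, 1])
            ph = phi[i + 1]
            if np.isnan(ph):
                ph = -139.0
            place(bb[i, 2], bb[i + 1, 0], bb[i + 1, 1], b_cac, a_ncac, ph,
                  bb[i + 1, 2])
        place(bb[i, 0], bb[i, 1], bb[i, 2], b_co, a_caco, psi_i + 180.0,
              bb[i, 3])
    return bb


try:
    import numba as _numba
    _nerf_chain = _numba.njit(cache=True)(_nerf_chain_py)
except Exception:  # pragma: no cover - numba present in supported envs
    _nerf_chain = _nerf_chain_py

_GEOM_VECTOR = None


def _geometry_vector():
    global _GEOM_VECTOR
    if _GEOM_VECTOR is None:
        g = GEOMETRY_TEMPLATE
        _GEOM_VECTOR = np.array([
            g["bond_N_CA"], g["bond_CA_C"], g["bond_C_N"], g["bond_C_O"],
            g["angle_N_CA_C"], g["angle_CA_C_N"], g["angle_C_N_CA"],
            g["angle_CA_C_O"]])
    return _GEOM_VECTOR


# --------------------------------------------------------------------------
# PDB I/O (via biotite)


def read_structure(path, chain: str = None) -> ProteinStructure:
    """Read the first (or selected) protein chain from a PDB file.

    Residues missing any of the four backbone atoms are dropped with a
    warning.  Real CB atoms are used where present; glycine (or any residue
    lacking CB) gets a pseudo-CB constructed from N/CA/C.
    """
    import biotite.structure as struc
    from biotite.structure.io.pdb import PDBFile

    try:
        pdb = PDBFile.read(str(path))
        atoms = pdb.get_structure(model=1)
    except Exception as exc:
        raise StructureError(f"cannot read PDB file {path}: {exc}") from exc

    atoms = atoms[struc.filter_amino_acids(atoms)]
    if atoms.array_length() == 0:
        raise StructureError(f"no protein chain in {path}")
    if chain is None:
        chain = atoms.chain_id[0]
    atoms = atoms[atoms.chain_id == chain]
    if atoms.array_length() == 0:
        raise StructureError(f"chain {chain!r} not found in {path}")

    seq, bb, cb, resseq = [], [], [], []
    for res_id in np.unique(atoms.res_id):
        res = atoms[atoms.res_id == res_id]
        names = list(res.atom_name)
        if any(a not in names for a in BACKBONE_ATOMS):
            warnings.warn(
                f"{path}: residue {res_id} missing backbone atoms, dropped")
            continue
        coords = np.array(
            [res.coord[names.index(a)] for a in BACKBONE_ATOMS])
        res_name = res.res_name[0]
        one = AA_3TO1.get(res_name, "X")
        if "CB" in names:
            cbx = res.coord[names.index("CB")]
        else:
            cbx = pseudo_cb(coords[0], coords[1], coords[2])
        seq.append(one)
        bb.append(coords)
        cb.append(cbx)
        resseq.append(res_id)
    if not seq:
        raise StructureError(f"no complete residues in {path}")
    sid = f"{path}" if chain is None else str(chain)
    return ProteinStructure(sid, "".join(seq), np.array(bb), np.array(cb),
                            np.array(resseq))


def write_structure(path, structures, chain: str = "A"):
    """Write one structure (or a list, as MODEL/ENDMDL frames) to PDB."""
    import biotite.structure as struc
    from biotite.structure.io.pdb import PDBFile

    if isinstance(structures, ProteinStructure):
        structures = [structures]
    ref = structures[0]
    L = len(ref)

    def to_atom_array(s):
        n_atoms = L * 5
        arr = struc.AtomArray(n_atoms)
        coords = np.empty((n_atoms, 3))
        k = 0
        for i in range(L):
            three = AA_1TO3.get(s.sequence[i], "UNK")
            for j, name in enumerate(BACKBONE_ATOMS):
                arr.atom_name[k] = name
                arr.element[k] = name[0]
                arr.res_name[k] = three
                arr.res_id[k] = s.resseq[i]
                arr.chain_id[k] = chain
                coords[k] = s.backbone[i, j]
                k += 1
            arr.atom_name[k] = "CB"
            arr.element[k] = "C"
            arr.res_name[k] = three
            arr.res_id[k] = s.resseq[i]
            arr.chain_id[k] = chain
            coords[k] = s.cb[i]
            k += 1
        arr.coord = coords
        arr.hetero[:] = False
        return arr

    pdb = PDBFile()
    if len(structures) == 1:
        pdb.set_structure(to_atom_array(structures[0]))
    else:
        stack = struc.stack([to_atom_array(s) for s in structures])
        pdb.set_structure(stack)
    pdb.write(str(path))


# --------------------------------------------------------------------------
# superposition and TM-score


def kabsch_superpose(mobile: np.ndarray, fixed: np.ndarray,
                     weights: np.ndarray = None) -> SuperpositionResult:
    """Least-squares rigid superposition of ``mobile`` onto ``fixed``.

    Returns the proper rotation/translation minimizing (weighted) RMSD.
    """
    mobile = np.asarray(mobile, float)
    fixed = np.asarray(fixed, float)
    if mobile.shape != fixed.shape or mobile.ndim != 2:
        raise ValueError("coordinate sets must have identical (n, 3) shapes")
    n = len(mobile)
    if n < 3:
        raise StructureError("superposition needs at least 3 points")
    if weights is None:
        weights = np.ones(n)
    w = weights / weights.sum()
    mc = (w[:, None] * mobile).sum(0)
    fc = (w[:, None] * fixed).sum(0)
    P = (mobile - mc) * w[:, None]
    Q = fixed - fc
    H = P.T @ Q
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = fc - R @ mc
    moved = mobile @ R.T + t
    rmsd = float(np.sqrt(((moved - fixed) ** 2).sum(-1).mean()))
    return SuperpositionResult(R, t, rmsd)


def tm_d0(l_ref: int) -> float:
    """Length-dependent TM-score normalization distance (floored at 0.5 A)."""
    if l_ref > 15:
        d0 = 1.24 * (l_ref - 15) ** (1.0 / 3.0) - 1.8
    else:
        d0 = 0.5
    return max(d0, 0.5)


def _tm_from_distances(d, d0, l_ref):
    return float(np.sum(1.0 / (1.0 + (d / d0) ** 2)) / l_ref)


def tm_superpose(mobile_ca: np.ndarray, fixed_ca: np.ndarray,
                 l_ref: int = None) -> SuperpositionResult:
    """TM-score-maximizing superposition by iterative inlier refinement.

    Seeds from the full alignment and from contiguous windows, then
    alternates Kabsch superposition on an inlier subset with subset
    re-selection at a shrinking distance cutoff, keeping the best-scoring
    transform.  This mirrors the heuristic search of the standard TM-score
    program at reduced cost.
    """
    mobile_ca = np.asarray(mobile_ca, float)
    fixed_ca = np.asarray(fixed_ca, float)
    n = len(mobile_ca)
    if n < 3:
        raise StructureError("TM superposition needs >= 3 aligned pairs")
    if l_ref is None:
        l_ref = n
    d0 = tm_d0(l_ref)

    seeds = [np.arange(n)]
    for wlen in sorted({max(n // 2, 4), max(n // 4, 4), 4}):
        if wlen >= n:
            continue
        for start in range(0, n - wlen + 1, max(wlen // 4, 1)):
            seeds.append(np.arange(start, start + wlen))

    best = None
    best_tm = -1.0
    for seed in seeds:
        if len(seed) < 3:
            continue
        idx = seed
        prev = None
        for cutoff in (8.0, 6.0, 5.0, 4.0, 3.5, max(3.0, d0 + 1.0),
                       max(3.0, d0 + 1.0), max(2.0, d0),
                       max(2.0, d0), max(2.0, d0)):
            sup = kabsch_superpose(mobile_ca[idx], fixed_ca[idx])
            d = np.linalg.norm(sup.apply(mobile_ca) - fixed_ca, axis=1)
            tm = _tm_from_distances(d, d0, l_ref)
            if tm > best_tm:
                best_tm = tm
                best = sup
            new_idx = np.where(d < cutoff)[0]
            if len(new_idx) < 3:
                # fall back to the closest 4 pairs to keep refining
                new_idx = np.argsort(d)[:4]
            if prev is not None and np.array_equal(new_idx, prev):
                break
            prev = idx = new_idx
    # polish: d0-weighted iterative reweighting from the best frame
    for _ in range(6):
        d = np.linalg.norm(best.apply(mobile_ca) - fixed_ca, axis=1)
        w = 1.0 / (1.0 + (d / d0) ** 2) ** 2
        sup = kabsch_superpose(mobile_ca, fixed_ca, weights=w)
        d = np.linalg.norm(sup.apply(mobile_ca) - fixed_ca, axis=1)
        tm = _tm_from_distances(d, d0, l_ref)
        if tm > best_tm:
            best_tm = tm
            best = sup
        else:
            break
    best.tm_score = best_tm
    best.rmsd = float(np.sqrt(
        ((best.apply(mobile_ca) - fixed_ca) ** 2).sum(-1).mean()))
    return best


def tm_score(model: ProteinStructure, reference: ProteinStructure,
             mapping=None) -> float:
    """TM-score of ``model`` against ``reference``, normalized by the
    reference length, maximized over rigid superpositions.

    ``mapping`` is a sequence of (model_index, reference_index) pairs;
    identity mapping is assumed when omitted (equal lengths required).
    """
    if mapping is None:
        if len(model) != len(reference):
            raise ValueError("identity mapping requires equal lengths")
        mapping = [(i, i) for i in range(len(model))]
    mapping = np.asarray(list(mapping), dtype=int)
    if len(mapping) < 3:
        raise StructureError("mapping shorter than 3 pairs")
    mob = model.ca[mapping[:, 0]]
    fix = reference.ca[mapping[:, 1]]
    sup = tm_superpose(mob, fix, l_ref=len(reference))
    return sup.tm_score


# --------------------------------------------------------------------------
# torsions <-> Cartesian


def measure_torsions(s: ProteinStructure) -> TorsionChain:
    """Measure backbone (phi, psi, omega) in degrees from coordinates.

    psi is measured via the carbonyl oxygen (psi = dihedral(N,CA,C,O) - 180),
    which is defined for every residue including the C-terminus; phi[0] and
    omega[0] are NaN.
    """
    L = len(s)
    N, CA, C, O = (s.backbone[:, i] for i in range(4))
    phi = np.full(L, np.nan)
    psi = np.full(L, np.nan)
    omega = np.full(L, np.nan)
    if L > 1:
        phi[1:] = _dihedral(C[:-1], N[1:], CA[1:], C[1:])
        omega[1:] = _dihedral(CA[:-1], C[:-1], N[1:], CA[1:])
    raw = _dihedral(N, CA, C, O) - 180.0
    psi[:] = (raw + 180.0) % 360.0 - 180.0
    return TorsionChain(phi, psi, omega, s.sequence)


def rebuild_cartesian(torsions: TorsionChain, sequence: str = None,
                      structure_id: str = "rebuilt") -> ProteinStructure:
    """Rebuild Cartesian backbone from torsions with ideal covalent geometry.

    Sequential NeRF placement: every bond length and bond angle equals the
    geometry template exactly, so torsions are the only degrees of freedom.
    """
    L = len(torsions)
    if sequence is None:
        sequence = torsions.sequence or "A" * L
    if len(sequence) != L:
        raise ValueError("sequence length does not match torsion chain")

    bb = _nerf_chain(np.ascontiguousarray(torsions.phi, dtype=float),
                     np.ascontiguousarray(torsions.psi, dtype=float),
                     np.ascontiguousarray(torsions.omega, dtype=float),
                     _geometry_vector())
    cb = pseudo_cb(bb[:, 0], bb[:, 1], bb[:, 2])
    return ProteinStructure(structure_id, sequence, bb, cb)


# --------------------------------------------------------------------------
# secondary structure, accessibility, compactness

_HELIX_PHI = (-120.0, -30.0)
_HELIX_PSI = (-80.0, -5.0)


def _in_helix_basin(phi, psi):
    return ((phi > _HELIX_PHI[0]) & (phi < _HELIX_PHI[1])
            & (psi > _HELIX_PSI[0]) & (psi < _HELIX_PSI[1]))


def _in_extended_basin(phi, psi):
    return (phi > -180.0) & (phi < -90.0) & (
        ((psi > 90.0) & (psi <= 180.0)) | (psi < -150.0))


def assign_secondary_structure(s: ProteinStructure) -> np.ndarray:
    """Per-residue H/E/C labels from dihedral basins + hydrogen-bond pattern.

    Helix: runs of >= 4 residues in the helical phi/psi basin containing an
    i -> i+4 O..N contact below 3.5 A.  Strand: runs of >= 3 residues in the
    extended basin.  Deterministic; no smoothing beyond the run rules.
    """
    L = len(s)
    t = measure_torsions(s)
    phi = np.where(np.isnan(t.phi), 1000.0, t.phi)
    psi = np.where(np.isnan(t.psi), 1000.0, t.psi)
    helical = _in_helix_basin(phi, psi)
    extended = _in_extended_basin(phi, psi)
    # treat the undefined first phi as agreeing with its neighbor
    if L > 1:
        helical[0] = helical[0] or (_in_helix_basin(1000.0, psi[0])
                                    and helical[1])
        extended[0] = extended[0] or False

    O = s.backbone[:, 3]
    N = s.backbone[:, 0]
    on_contact = np.zeros(L, dtype=bool)  # O(i)..N(i+4) < 3.5
    if L > 4:
        d = np.linalg.norm(O[:-4] - N[4:], axis=1)
        on_contact[:-4] = d < 3.5

    labels = np.full(L, "C", dtype="<U1")
    # helix runs
    i = 0
    while i < L:
        if helical[i]:
            j = i
            while j < L and helical[j]:
                j += 1
            if j - i >= 4 and on_contact[i:j].any():
                labels[i:j] = "H"
            i = j
        else:
            i += 1
    # strand runs (do not overwrite helix)
    i = 0
    while i < L:
        if extended[i] and labels[i] == "C":
            j = i
            while j < L and extended[j] and labels[j] == "C":
                j += 1
            if j - i >= 3:
                labels[i:j] = "E"
            i = j
        else:
            i += 1
    return labels


def _sphere_dots(n: int) -> np.ndarray:
    """Quasi-uniform unit sphere dots (golden-spiral construction)."""
    k = np.arange(n) + 0.5
    z = 1.0 - 2.0 * k / n
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, 1.0))
    theta = np.pi * (1.0 + np.sqrt(5.0)) * k
    return np.stack([r * np.cos(theta), r * np.sin(theta), z], axis=1)


def relative_solvent_accessibility(s: ProteinStructure) -> np.ndarray:
    """Relative solvent accessibility per residue, clipped to [0, 1.2].

    Sphere-dot (Shrake–Rupley-style) accessible surface area over the
    reduced atom set (backbone + CB), divided by a residue-specific maximum
    accessibility.  An approximation to all-atom DSSP accessibility: the
    reduced atom set under-occludes, so absolute values are generous, but
    buried/exposed contrast is preserved.
    """
    coords, res_idx, names = s.all_atoms()
    radii = np.array([_ASA_RADII[n] for n in names]) + _ASA_PROBE
    n_atoms = len(coords)
    dots = _sphere_dots(_ASA_N_DOTS)

    from scipy.spatial import cKDTree
    tree = cKDTree(coords)
    max_reach = 2 * radii.max()
    asa_atom = np.empty(n_atoms)
    for a in range(n_atoms):
        pts = coords[a] + radii[a] * dots
        neigh = [b for b in tree.query_ball_point(coords[a], max_reach)
                 if b != a]
        if neigh:
            d = np.linalg.norm(pts[:, None, :] - coords[neigh][None, :, :],
                               axis=2)
            exposed = (d >= radii[neigh][None, :]).all(axis=1)
        else:
            exposed = np.ones(_ASA_N_DOTS, dtype=bool)
        asa_atom[a] = (4.0 * np.pi * radii[a] ** 2
                       * exposed.sum() / _ASA_N_DOTS)

    L = len(s)
    rsa = np.empty(L)
    for i in range(L):
        asa = asa_atom[res_idx == i].sum()
        rsa[i] = asa / MAX_ASA.get(s.sequence[i], 200.0)
    return np.clip(rsa, 0.0, 1.2)


def radius_of_gyration(s: ProteinStructure) -> float:
    """Root-mean-square CA distance from the CA centroid, in Angstrom."""
    ca = s.ca
    if len(ca) == 0:
        raise StructureError("empty structure")
    centroid = ca.mean(0)
    return float(np.sqrt(((ca - centroid) ** 2).sum(-1).mean()))
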