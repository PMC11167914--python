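"""Evolutionary folding information extracted from the MSTA.

The per-residue conservation statistic (F value) is the mean, over the N
homologs of the MSTA, of a binned score of how closely the homolog residue
superposes onto the target residue: deviations within 2 A score 1, within
(2, 4] A score 0.75, within (4, 5] A score 0.25, beyond 5 A (or unaligned)
score 0.  F close to 1 therefore marks positions that recur at the same
place across the structural family — the evolutionarily conserved, early
folding core.

F values feed two downstream objects: pair weights (harmonic mean of the
two residues' F values) and the distance-restraint map taken from the
target's 3D model, with a log(|i-j|) normalizer that de-emphasizes
sequence-distant pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .structio import ProteinStructure
from .msta import MSTA, AlignmentError

__all__ = [
    "FValueProfile",
    "RestraintMap",
    "DEVIATION_BINS",
    "BIN_SCORES",
    "residue_frequency_scores",
    "pair_weights",
    "restraint_map",
    "write_f_profile",
]

#: deviation thresholds (A) and the score of each bin, highest first
DEVIATION_BINS = (2.0, 4.0, 5.0)
BIN_SCORES = (1.0, 0.75, 0.25, 0.0)

DEFAULT_EPSILON = 1e-3
DEFAULT_MIN_SEPARATION = 2


@dataclass
class FValueProfile:
    f: np.ndarray
    n_homologs: int
    bins: tuple = DEVIATION_BINS
    scores: tuple = BIN_SCORES

    def __post_init__(self):
        self.f = np.asarray(self.f, dtype=float)

    def __len__(self):
        return len(self.f)


@dataclass
class RestraintMap:
    """Target distances plus weights for the statistical potential.

    ``d`` is the CA–CA distance matrix of the target model, ``dstar`` the
    log(eps + |i-j|) normalizer, ``w`` the F-derived pair weights and
    ``mask`` marks the (i < j, |i-j| >= min_separation) pairs entering
    the energy sums.
    """

    d: np.ndarray
    dstar: np.ndarray
    w: np.ndarray
    epsilon: float = DEFAULT_EPSILON
    min_separation: int = DEFAULT_MIN_SEPARATION
    mask: np.ndarray = field(default=None)

    def __post_init__(self):
        L = len(self.d)
        if self.mask is None:
            i, j = np.meshgrid(np.arange(L), np.arange(L), indexing="ij")
            self.mask = (j > i) & (np.abs(i - j) >= self.min_separation)

    def __len__(self):
        return len(self.d)


def deviation_score(d):
    """Binned conservation score of a deviation distance; NaN scores 0."""
    d = np.asarray(d, dtype=float)
    out = np.zeros(d.shape)
    valid = ~np.isnan(d)
    out = np.where(valid & (d <= DEVIATION_BINS[0]), BIN_SCORES[0], out)
    out = np.where(valid & (d > DEVIATION_BINS[0])
                   & (d <= DEVIATION_BINS[1]), BIN_SCORES[1], out)
    out = np.where(valid & (d > DEVIATION_BINS[1])
                   & (d <= DEVIATION_BINS[2]), BIN_SCORES[2], out)
    return out


def residue_frequency_scores(msta: MSTA) -> FValueProfile:
    """Per-residue F values: mean binned deviation score over the MSTA.

    Unaligned target positions count 0 for that homolog, so F stays
    normalized by the homolog count N.
    """
    if msta.n < 1:
        raise AlignmentError("MSTA has no homologs")
    scores = np.stack([deviation_score(h.deviations)
                       for h in msta.homologs])
    return FValueProfile(scores.mean(axis=0), msta.n)


def pair_weights(f: FValueProfile) -> np.ndarray:
    """Symmetric pair-weight matrix: harmonic mean of F_i and F_j.

    Defined as 0 where F_i + F_j = 0.  The harmonic mean is bounded by
    [min(F_i, F_j), max(F_i, F_j)], so weights inherit the [0, 1] range.
    """
    fv = np.asarray(f.f if isinstance(f, FValueProfile) else f, dtype=float)
    s = fv[:, None] + fv[None, :]
    with np.errstate(divide="ignore", invalid="ignore"):
        w = np.where(s > 0, 2.0 * fv[:, None] * fv[None, :] / s, 0.0)
    return w


def restraint_map(target_model: ProteinStructure, f: FValueProfile,
                  epsilon: float = DEFAULT_EPSILON,
                  min_separation: int = DEFAULT_MIN_SEPARATION
                  ) -> RestraintMap:
    """Build the restraint map from the target 3D model and the F profile.

    Adjacent-pair distances are fixed by covalent geometry and carry no
    folding signal, hence the default minimum sequence separation of 2;
    epsilon keeps the log normalizer finite there anyway.
    """
    from scipy.spatial.distance import squareform, pdist

    ca = target_model.ca
    L = len(target_model)
    d = squareform(pdist(ca))
    idx = np.arange(L)
    sep = np.abs(idx[:, None] - idx[None, :])
    dstar = np.log(epsilon + sep)
    w = pair_weights(f)
    rm = RestraintMap(d, dstar, w, epsilon, min_separation)
    return rm


def write_f_profile(path, f: FValueProfile):
    """Two-column TSV: 1-based residue index, F value."""
    with open(path, "w") as fh:
        fh.write("# residue\tF\n")
        for i, v in enumerate(f.f, start=1):
            fh.write(f"{i}\t{v:.6f}\n")
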