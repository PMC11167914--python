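"""Position-specific folding fragment libraries.

Fragments are 3- and 6-residue torsion windows cut from MSTA candidate
structures.  Before extraction the most target-identical homologs are
removed: M = floor(N * min_i F_i) structures, ranked by TM-score, carry no
folding information (they are near-copies of the target), while the
remaining candidates are locally identical in conserved regions and diverse
in flexible ones — which is exactly the signal fragment assembly exploits.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .structio import measure_torsions
from .msta import MSTA
from .foldinfo import FValueProfile

__all__ = [
    "Fragment",
    "FragmentLibrary",
    "FragmentError",
    "redundancy_cut",
    "extract_fragments",
    "sample_fragment",
    "build_library",
    "write_library",
]

FRAGMENT_LENGTHS = (3, 6)
_DEDUP_DECIMALS = 2  # torsion tuples equal within 1e-2 deg collapse


class FragmentError(ValueError):
    pass


@dataclass
class Fragment:
    target_start: int
    length: int
    torsions: np.ndarray  # (length, 3) phi/psi/omega in degrees
    source_id: str = ""

    def __post_init__(self):
        self.torsions = np.asarray(self.torsions, dtype=float)
        if self.length not in FRAGMENT_LENGTHS:
            raise FragmentError(f"fragment length {self.length} not in "
                                f"{FRAGMENT_LENGTHS}")
        if self.torsions.shape != (self.length, 3):
            raise FragmentError("torsions shape mismatch")


@dataclass
class FragmentLibrary:
    frags3: dict = field(default_factory=dict)   # position -> [Fragment]
    frags6: dict = field(default_factory=dict)
    m_removed: int = 0
    candidate_ids: list = field(default_factory=list)

    def by_length(self, length: int) -> dict:
        if length == 3:
            return self.frags3
        if length == 6:
            return self.frags6
        raise FragmentError(f"no library for length {length}")

    def n_fragments(self, length: int = None) -> int:
        if length is None:
            return self.n_fragments(3) + self.n_fragments(6)
        return sum(len(v) for v in self.by_length(length).values())


def redundancy_cut(msta: MSTA, f: FValueProfile) -> list:
    """Drop the top M = floor(N * min F) most target-identical homologs.

    Homologs are ranked by TM-score (descending, stable under ties) and the
    top M removed; the survivors are the fragment candidates.
    """
    n = msta.n
    if n < 1:
        raise FragmentError("MSTA has no homologs")
    m = int(np.floor(n * float(np.min(f.f))))
    if m >= n:
        raise FragmentError(
            f"redundancy cut removed every structure (M={m}, N={n}); "
            "the MSTA is uniformly identical to the target")
    order = sorted(range(n), key=lambda i: -msta.homologs[i].tm_score)
    keep = sorted(order[m:])
    candidates = [msta.homologs[i] for i in keep]
    return candidates, m


def _maximal_blocks(mapping: np.ndarray):
    """Maximal alignment blocks consecutive in both target and homolog."""
    blocks = []
    start = 0
    for k in range(1, len(mapping) + 1):
        if (k == len(mapping)
                or mapping[k, 0] != mapping[k - 1, 0] + 1
                or mapping[k, 1] != mapping[k - 1, 1] + 1):
            blocks.append(mapping[start:k])
            start = k
    return blocks


def extract_fragments(candidates, target_length: int) -> FragmentLibrary:
    """Cut all 3- and 6-residue windows from maximal aligned blocks.

    Torsions are measured on the homolog chain; windows are keyed by the
    target start position.  Blocks shorter than 3 contribute nothing;
    blocks of length 3-5 contribute only 3-mers.  Per-position lists are
    deduplicated by rounded torsion tuple to bound memory.
    """
    lib = FragmentLibrary(candidate_ids=[c.structure.id for c in candidates])
    seen = {3: set(), 6: set()}
    for cand in candidates:
        t = measure_torsions(cand.structure)
        tor = np.stack([t.phi, t.psi, t.omega], axis=1)
        # chain-terminal undefined angles default to extended values
        tor[np.isnan(tor[:, 0]), 0] = -139.0
        tor[np.isnan(tor[:, 2]), 2] = 180.0
        for block in _maximal_blocks(cand.mapping):
            for length in FRAGMENT_LENGTHS:
                if len(block) < length:
                    continue
                store = lib.by_length(length)
                for k in range(len(block) - length + 1):
                    tstart = int(block[k, 0])
                    hstart = int(block[k, 1])
                    if tstart + length > target_length:
                        continue
                    window = tor[hstart:hstart + length]
                    key = (tstart,
                           tuple(np.round(window, _DEDUP_DECIMALS).ravel()))
                    if key in seen[length]:
                        continue
                    seen[length].add(key)
                    store.setdefault(tstart, []).append(
                        Fragment(tstart, length, window.copy(),
                                 cand.structure.id))
    return lib


def sample_fragment(lib: FragmentLibrary, length: int, rng,
                    position: int = None) -> Fragment:
    """Draw a fragment uniformly: first a position among those covered,
    then a fragment within the position.  Deterministic under a fixed rng
    state."""
    store = lib.by_length(length)
    if position is None:
        positions = sorted(store)
        if not positions:
            raise FragmentError(f"no {length}-mer fragment at any position")
        position = positions[rng.integers(len(positions))]
    frags = store.get(position)
    if not frags:
        raise FragmentError(f"no {length}-mer fragment at position "
                            f"{position}")
    return frags[rng.integers(len(frags))]


def build_library(msta: MSTA, f: FValueProfile,
                  allow_identical: bool = True) -> FragmentLibrary:
    """Redundancy cut + extraction in one step.

    When the MSTA is uniformly identical to the target the cut removes
    everything; with ``allow_identical`` the cut is skipped in that case so
    a library still exists (the fragments are then simply the target's own
    torsions).
    """
    try:
        candidates, m = redundancy_cut(msta, f)
    except FragmentError:
        if not allow_identical:
            raise
        candidates, m = list(msta.homologs), 0
    lib = extract_fragments(candidates, len(msta.target))
    lib.m_removed = m
    return lib


def write_library(path, lib: FragmentLibrary):
    """Flat TSV: position (1-based), length, source, phi/psi/omega columns."""
    with open(path, "w") as fh:
        fh.write("# position\tlength\tsource\ttorsions(phi,psi,omega;...)\n")
        for length in FRAGMENT_LENGTHS:
            for pos in sorted(lib.by_length(length)):
                for frag in lib.by_length(length)[pos]:
                    tor = ";".join(
                        ",".join(f"{x:.2f}" for x in row)
                        for row in frag.torsions)
                    fh.write(f"{pos + 1}\t{length}\t{frag.source_id}\t"
                             f"{tor}\n")
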