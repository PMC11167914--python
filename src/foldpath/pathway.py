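"""Trajectory analysis: intermediates, per-region lDDT and folding order.

The nucleation-stage snapshot stream is clustered (greedy leader
clustering on CA-RMSD) into intermediate ensembles.  Each intermediate is
scored against the native structure with lDDT restricted to the annotated
early-folded region (EFR) and its complement (LFR); the predicted folding
order is called consistent with experiment when lDDT(EFR) exceeds
lDDT(LFR) by at least 0.10 lDDT units.  An ensemble overlap profile
(min-max normalized mean pairwise per-residue deviation) colors which
residues converge first, and per-stage secondary-structure / burial /
compactness statistics summarize the folding process.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .structio import (ProteinStructure, kabsch_superpose, tm_score,
                       assign_secondary_structure,
                       relative_solvent_accessibility, radius_of_gyration)

__all__ = [
    "RegionAnnotation",
    "PathwayReport",
    "lddt",
    "cluster_intermediates",
    "fold_order_call",
    "rmsd_norm_profile",
    "stage_statistics",
    "analyze_trajectory",
]

FOLD_ORDER_MARGIN = 0.10
LDDT_RADIUS = 15.0
LDDT_THRESHOLDS = (0.5, 1.0, 2.0, 4.0)
BURIED_RSA = 0.25
DEFAULT_CLUSTER_CUTOFF = 3.0


@dataclass
class RegionAnnotation:
    """EFR residue ranges, 1-based inclusive; LFR is the complement."""

    efr_ranges: list   # [(start, end)] 1-based inclusive
    length: int

    def __post_init__(self):
        taken = np.zeros(self.length, dtype=bool)
        for a, b in self.efr_ranges:
            if not (1 <= a <= b <= self.length):
                raise ValueError(f"range {a}-{b} outside 1..{self.length}")
            if taken[a - 1:b].any():
                raise ValueError("overlapping EFR ranges")
            taken[a - 1:b] = True
        self._efr_mask = taken

    @property
    def efr(self) -> np.ndarray:
        """0-based EFR residue indices."""
        return np.where(self._efr_mask)[0]

    @property
    def lfr(self) -> np.ndarray:
        return np.where(~self._efr_mask)[0]

    @classmethod
    def from_string(cls, ranges: str, length: int):
        """Parse '12-45,60-71' into an annotation."""
        parsed = []
        for part in ranges.split(","):
            a, b = part.strip().split("-")
            parsed.append((int(a), int(b)))
        return cls(parsed, length)

    @classmethod
    def read_tsv(cls, path, length: int, case_id: str = None):
        with open(path) as fh:
            for line in fh:
                if line.startswith("#") or not line.strip():
                    continue
                cid, ranges = line.split("\t")[:2]
                if case_id is None or cid == case_id:
                    return cls.from_string(ranges.strip(), length)
        raise ValueError(f"no annotation for {case_id!r} in {path}")


def lddt(model: ProteinStructure, reference: ProteinStructure,
         subset=None, inclusion_radius: float = LDDT_RADIUS,
         thresholds=LDDT_THRESHOLDS, min_separation: int = 2) -> float:
    """Superposition-free local distance difference test on CA atoms.

    Qualifying pairs: reference CA-CA distance below the inclusion radius,
    sequence separation >= 2, and (when ``subset`` is given) at least one
    endpoint in the subset.  The preserved fraction is averaged over the
    four tolerance thresholds.
    """
    if len(model) != len(reference):
        raise ValueError("model/reference length mismatch")
    L = len(reference)
    d_ref = squareform(pdist(reference.ca))
    d_mod = squareform(pdist(model.ca))
    idx = np.arange(L)
    sep = np.abs(idx[:, None] - idx[None, :])
    qual = (d_ref < inclusion_radius) & (sep >= min_separation)
    qual &= np.triu(np.ones((L, L), dtype=bool), k=1)
    if subset is not None:
        subset = np.asarray(list(subset), dtype=int)
        if subset.size == 0:
            raise ValueError("empty subset")
        in_subset = np.zeros(L, dtype=bool)
        in_subset[subset] = True
        qual &= in_subset[:, None] | in_subset[None, :]
    n_pairs = int(qual.sum())
    if n_pairs == 0:
        return 1.0
    diff = np.abs(d_ref[qual] - d_mod[qual])
    preserved = sum((diff < t).mean() for t in thresholds) / len(thresholds)
    return float(preserved)


@dataclass
class IntermediateEnsemble:
    representative: ProteinStructure
    members: list
    size: int


def cluster_intermediates(structures, rmsd_cutoff: float =
                          DEFAULT_CLUSTER_CUTOFF):
    """Greedy leader clustering on pairwise CA-RMSD after superposition.

    The first structure seeds cluster 1; each subsequent joins the first
    cluster whose leader it matches within the cutoff, else seeds a new
    cluster.  Representatives minimize summed RMSD to co-members; clusters
    are returned largest first (ties keep formation order).
    """
    structures = list(structures)
    if not structures:
        raise ValueError("no snapshots to cluster")

    def ca_rmsd(a, b):
        return kabsch_superpose(a.ca, b.ca).rmsd

    leaders = []
    clusters = []
    for s in structures:
        placed = False
        for k, leader in enumerate(leaders):
            if ca_rmsd(s, leader) <= rmsd_cutoff:
                clusters[k].append(s)
                placed = True
                break
        if not placed:
            leaders.append(s)
            clusters.append([s])

    ensembles = []
    for members in clusters:
        if len(members) == 1:
            rep = members[0]
        else:
            sums = [sum(ca_rmsd(m, o) for o in members) for m in members]
            rep = members[int(np.argmin(sums))]
        ensembles.append(IntermediateEnsemble(rep, members, len(members)))
    ensembles.sort(key=lambda e: -e.size)
    return ensembles


def fold_order_call(intermediate: ProteinStructure,
                    native: ProteinStructure,
                    annotation: RegionAnnotation):
    """Score the intermediate's EFR and LFR against the native structure.

    The folding order is called consistent when lDDT(EFR) exceeds
    lDDT(LFR) by at least 0.10 lDDT units (boundary inclusive).
    """
    if annotation.length != len(native):
        raise ValueError("annotation length does not match native")
    lddt_efr = lddt(intermediate, native, subset=annotation.efr)
    lddt_lfr = lddt(intermediate, native, subset=annotation.lfr)
    consistent = (lddt_efr - lddt_lfr) >= FOLD_ORDER_MARGIN - 1e-12
    return lddt_efr, lddt_lfr, bool(consistent)


def rmsd_norm_profile(ensemble) -> np.ndarray:
    """Per-residue ensemble overlap in [0, 1]; 0 = residues that coincide
    across the ensemble (fold first), 1 = most divergent.

    Every member pair is superposed independently (pairwise Kabsch, which
    is symmetric), the per-residue CA deviations are averaged over all
    pairs and min-max normalized over residues — so the profile does not
    depend on member order.  A perfectly coincident ensemble maps to all
    zeros.
    """
    members = [m.structure if hasattr(m, "structure") else m
               for m in ensemble]
    if len(members) < 2:
        raise ValueError("ensemble needs at least 2 members")
    cas = [m.ca for m in members]
    n = len(cas)
    total = np.zeros(len(cas[0]))
    count = 0
    for a in range(n):
        for b in range(a + 1, n):
            sup = kabsch_superpose(cas[b], cas[a])
            total += np.linalg.norm(sup.apply(cas[b]) - cas[a], axis=1)
            count += 1
    raw = total / count
    span = raw.max() - raw.min()
    if span <= 1e-8:
        return np.zeros_like(raw)
    return (raw - raw.min()) / span


def stage_statistics(trajectory) -> dict:
    """Per-stage mean helix/sheet fraction and buried fraction plus the
    full Rg series (one value per snapshot)."""
    stats = {"rg_series": [s.rg for s in trajectory.snapshots]}
    for stage in ("init", "nucleation", "finalization"):
        snaps = trajectory.stage_snapshots(stage)
        if not snaps:
            continue
        helix, sheet, buried = [], [], []
        for s in snaps:
            labels = assign_secondary_structure(s.structure)
            helix.append(float(np.mean(labels == "H")))
            sheet.append(float(np.mean(labels == "E")))
        # burial is expensive; sample a few snapshots evenly
        pick = snaps[:: max(len(snaps) // 5, 1)]
        for s in pick:
            rsa = relative_solvent_accessibility(s.structure)
            buried.append(float(np.mean(rsa < BURIED_RSA)))
        stats[stage] = {
            "helix_fraction": float(np.mean(helix)),
            "sheet_fraction": float(np.mean(sheet)),
            "buried_fraction": float(np.mean(buried)),
        }
    return stats


@dataclass
class PathwayReport:
    intermediates: list
    lddt_efr: float = None
    lddt_lfr: float = None
    consistent: bool = None
    final_tm_score: float = None
    rmsd_norm: np.ndarray = None
    stage_stats: dict = field(default_factory=dict)

    def to_dict(self):
        out = {
            "n_intermediates": len(self.intermediates),
            "intermediate_sizes": [e.size for e in self.intermediates],
            "stage_stats": self.stage_stats,
        }
        if self.lddt_efr is not None:
            out.update({"lddt_efr": self.lddt_efr,
                        "lddt_lfr": self.lddt_lfr,
                        "consistent": self.consistent})
        if self.final_tm_score is not None:
            out["final_tm_score"] = self.final_tm_score
        if self.rmsd_norm is not None:
            out["rmsd_norm"] = [float(x) for x in self.rmsd_norm]
        return out

    def write_json(self, path):
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def analyze_trajectory(trajectory, native: ProteinStructure = None,
                       annotation: RegionAnnotation = None,
                       rmsd_cutoff: float = DEFAULT_CLUSTER_CUTOFF
                       ) -> PathwayReport:
    """Cluster nucleation-stage snapshots into intermediates and, when a
    native reference (and annotation) is available, score folding order
    and final-state similarity."""
    nuc = [s.structure for s in trajectory.stage_snapshots("nucleation")]
    if not nuc:
        nuc = [trajectory.final]
    intermediates = cluster_intermediates(nuc, rmsd_cutoff)
    report = PathwayReport(intermediates)
    report.stage_stats = stage_statistics(trajectory)
    if len(intermediates[0].members) >= 2:
        report.rmsd_norm = rmsd_norm_profile(intermediates[0].members)
    if native is not None:
        report.final_tm_score = tm_score(trajectory.final, native)
        if annotation is not None:
            efr, lfr, ok = fold_order_call(intermediates[0].representative,
                                           native, annotation)
            report.lddt_efr, report.lddt_lfr, report.consistent = efr, lfr, ok
    return report
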