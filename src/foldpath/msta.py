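"""Multiple structure alignment (MSTA) construction.

Homologous structures are either ingested from a precomputed tabular hit
file (Foldseek-style TSV with CIGAR alignment strings) or aligned internally
by sequence (Needleman–Wunsch, BLOSUM62, affine gaps) followed by iterative
structural superposition.  Candidates below the TM-score retention threshold
(default 0.3) are removed, and per-target-residue deviation distances are
measured under the TM-score-optimal superposition — the inlier-weighted
frame emphasizes the conserved core, which the conservation statistic
downstream depends on.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .structio import (ProteinStructure, StructureError, read_structure,
                       tm_superpose, tm_d0)

__all__ = [
    "AlignedHomolog",
    "MSTA",
    "DEFAULT_LAMBDA",
    "load_hits_tsv",
    "build_msta",
    "align_fallback",
]

#: TM-score retention threshold for homologs entering the MSTA.
DEFAULT_LAMBDA = 0.3

HITS_COLUMNS = ["query", "target", "qstart", "qend", "tstart", "tend",
                "cigar", "evalue", "bits"]


class AlignmentError(ValueError):
    pass


@dataclass
class AlignedHomolog:
    """A homolog structure with its residue correspondence to the target.

    ``mapping`` holds (target_index, homolog_index) pairs, 0-based, strictly
    increasing in both columns.  ``deviations`` has one entry per *target*
    residue: the CA–CA Euclidean distance to the corresponding homolog
    residue after superposition, NaN where the target residue is unaligned.
    """

    structure: ProteinStructure
    mapping: np.ndarray
    tm_score: float = None
    deviations: np.ndarray = None

    def __post_init__(self):
        self.mapping = np.asarray(self.mapping, dtype=int).reshape(-1, 2)
        if len(self.mapping) > 1:
            if not (np.all(np.diff(self.mapping[:, 0]) > 0)
                    and np.all(np.diff(self.mapping[:, 1]) > 0)):
                raise AlignmentError("mapping must be strictly increasing "
                                     "in both columns")


@dataclass
class MSTA:
    target: ProteinStructure
    homologs: list = field(default_factory=list)
    lambda_threshold: float = DEFAULT_LAMBDA

    @property
    def n(self) -> int:
        return len(self.homologs)


def _decode_cigar(cigar: str, qstart: int, tstart: int):
    """Decode a CIGAR string into (query_index, hit_index) 0-based pairs.

    M advances both sequences, I advances the query only, D advances the
    hit only (BLAST/Foldseek convention for query-vs-target alignments).
    """
    ops = re.findall(r"(\d+)([MIDmid=X])", cigar)
    if not ops or "".join(f"{n}{o}" for n, o in ops) != cigar:
        raise AlignmentError(f"malformed CIGAR {cigar!r}")
    qi, ti = qstart - 1, tstart - 1
    pairs = []
    for count, op in ops:
        count = int(count)
        op = op.upper()
        if op in ("M", "=", "X"):
            for _ in range(count):
                pairs.append((qi, ti))
                qi += 1
                ti += 1
        elif op == "I":
            qi += count
        elif op == "D":
            ti += count
    return np.array(pairs, dtype=int)


def _superpose_and_deviations(target: ProteinStructure,
                              homolog: ProteinStructure,
                              mapping: np.ndarray):
    """TM-optimal superposition of the homolog onto the target; returns
    (tm_score, per-target-residue deviation array with NaN off-alignment)."""
    mob = homolog.ca[mapping[:, 1]]
    fix = target.ca[mapping[:, 0]]
    sup = tm_superpose(mob, fix, l_ref=len(target))
    d = np.linalg.norm(sup.apply(mob) - fix, axis=1)
    deviations = np.full(len(target), np.nan)
    deviations[mapping[:, 0]] = d
    return sup.tm_score, deviations


def load_hits_tsv(path, target: ProteinStructure, structure_dir) -> list:
    """Ingest a Foldseek-style hit table into aligned homologs.

    The TSV (no header) carries columns query, target, qstart, qend, tstart,
    tend, cigar, evalue, bits; hit structures are read from
    ``structure_dir/<target>.pdb``.  Malformed rows and missing files are
    skipped with a warning; an empty result raises.
    """
    import pandas as pd

    structure_dir = Path(structure_dir)
    try:
        df = pd.read_csv(path, sep="\t", names=HITS_COLUMNS, header=None,
                         comment="#")
    except pd.errors.EmptyDataError:
        df = None
    if df is None or len(df) == 0:
        raise AlignmentError(f"no hits in {path}")

    homologs = []
    for row in df.itertuples(index=False):
        pdb_path = structure_dir / f"{row.target}.pdb"
        if not pdb_path.exists():
            warnings.warn(f"hit structure {pdb_path} not found, row skipped")
            continue
        try:
            mapping = _decode_cigar(str(row.cigar), int(row.qstart),
                                    int(row.tstart))
        except AlignmentError as exc:
            warnings.warn(f"row for {row.target}: {exc}; skipped")
            continue
        structure = read_structure(pdb_path)
        structure.id = str(row.target)
        mapping = mapping[(mapping[:, 0] < len(target))
                          & (mapping[:, 1] < len(structure))]
        if len(mapping) < 3:
            warnings.warn(f"row for {row.target}: <3 aligned pairs; skipped")
            continue
        tm, dev = _superpose_and_deviations(target, structure, mapping)
        homologs.append(AlignedHomolog(structure, mapping, tm, dev))
    if not homologs:
        raise AlignmentError(f"all rows of {path} were skipped")
    return homologs


def build_msta(target: ProteinStructure, candidates,
               lambda_threshold: float = DEFAULT_LAMBDA) -> MSTA:
    """Filter candidates by TM-score and finalize deviation distances.

    TM-scores are recomputed from the stored mappings; candidates below the
    threshold are dropped (input order preserved among survivors) and the
    deviations of survivors are re-measured under the TM-score-optimal
    superposition.
    """
    survivors = []
    for cand in candidates:
        tm, dev = _superpose_and_deviations(target, cand.structure,
                                            cand.mapping)
        if tm >= lambda_threshold:
            survivors.append(AlignedHomolog(cand.structure, cand.mapping,
                                            tm, dev))
    if not survivors:
        raise AlignmentError(
            f"no homolog passed TM-score >= {lambda_threshold} "
            f"({len(list(candidates))} candidates filtered out)")
    return MSTA(target, survivors, lambda_threshold)


_ALIGNER = None


def _get_aligner():
    global _ALIGNER
    if _ALIGNER is None:
        from Bio import Align
        from Bio.Align import substitution_matrices
        a = Align.PairwiseAligner()
        a.substitution_matrix = substitution_matrices.load("BLOSUM62")
        a.open_gap_score = -11.0
        a.extend_gap_score = -1.0
        a.mode = "global"
        a.end_open_gap_score = -0.5
        a.end_extend_gap_score = -0.1
        _ALIGNER = a
    return _ALIGNER


def align_fallback(target: ProteinStructure,
                   homolog: ProteinStructure) -> AlignedHomolog:
    """Sequence-alignment + superposition stand-in for an external
    structure aligner; adequate for homologs with recognizable sequence
    similarity (fixtures, close families)."""
    if len(target) == 0 or len(homolog) == 0:
        raise AlignmentError("empty structure")
    aligner = _get_aligner()
    alignment = aligner.align(target.sequence, homolog.sequence)[0]
    pairs = []
    for (qs, qe), (ts, te) in zip(*alignment.aligned):
        for k in range(qe - qs):
            pairs.append((qs + k, ts + k))
    mapping = np.array(pairs, dtype=int)
    if len(mapping) < 3:
        raise AlignmentError("alignment produced fewer than 3 matched pairs")
    tm, dev = _superpose_and_deviations(target, homolog, mapping)
    return AlignedHomolog(homolog, mapping, tm, dev)
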