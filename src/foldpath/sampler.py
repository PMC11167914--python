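"""Three-stage Monte Carlo fragment-assembly engine.

The chain starts fully extended and folds through three stages:

1. *Initialization* — 20·L trial 3-mer insertions scored by the stage-1
   physical potential (steric + short-range hydrogen bonding) under the
   Metropolis criterion at kT_physi.  Individual helices and local hairpins
   form here.
2. *Folding nucleation* — 6-mer moves for the first half of the iterations,
   3-mer moves for the second half.  A trial must pass the Metropolis test
   for the conservation-weighted statistical potential at kT_stati AND for
   the stage-2 physical potential at kT_physi, so restraint satisfaction
   cannot be bought with physically unreasonable conformations.  High-F
   (conserved) residue pairs are pulled toward their target distances
   first: this is where the folding nucleus appears.
3. *Structure finalization* — same move schedule; the unweighted
   statistical potential is tried first and, if its Metropolis test fails,
   the stage-2 physical potential gets a second chance (a greedy OR that
   raises the acceptance rate and speeds convergence of low-F regions).

Both temperatures are held constant by default (kT_physi = 5, kT_stati = 2);
an optional geometric cooling factor is available.  A single seeded
generator drives every stochastic choice and is recorded in the run
manifest, so trajectories replay bit-exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .structio import (ProteinStructure, TorsionChain, rebuild_cartesian,
                       radius_of_gyration, write_structure)
from .msta import MSTA
from .foldinfo import (residue_frequency_scores, restraint_map, RestraintMap,
                       DEFAULT_EPSILON, DEFAULT_MIN_SEPARATION)
from .fragments import FragmentLibrary, sample_fragment, build_library
from .forcefield import EnergyWeights, physical_energy, statistical_energy

__all__ = [
    "SamplerConfig",
    "TrajectorySnapshot",
    "Trajectory",
    "metropolis_accept",
    "extended_chain",
    "initialize_stage",
    "nucleation_stage",
    "finalization_stage",
    "run_pipeline",
]

EXTENDED_PHI, EXTENDED_PSI, EXTENDED_OMEGA = -139.0, 135.0, 180.0

STAGES = ("init", "nucleation", "finalization")


@dataclass
class SamplerConfig:
    """Sampler knobs.  Iteration counts default to multiples of the chain
    length L: 20·L initialization trials (fixed by the protocol), 50·L
    nucleation and 30·L finalization iterations (package defaults, chosen
    so toy chains converge in minutes)."""

    seed: int = 0
    n_init: int = None            # default 20 * L
    n_nucleation: int = None      # default 50 * L
    n_finalization: int = None    # default 30 * L
    kT_physi: float = 5.0
    kT_stati: float = 2.0
    cooling: float = 1.0          # per-iteration geometric factor
    stride: int = 10
    lambda_threshold: float = 0.3
    epsilon: float = DEFAULT_EPSILON
    min_separation: int = DEFAULT_MIN_SEPARATION

    def resolve(self, L: int):
        return replace_defaults(self, L)


def replace_defaults(cfg: SamplerConfig, L: int) -> SamplerConfig:
    from dataclasses import replace
    return replace(
        cfg,
        n_init=cfg.n_init if cfg.n_init is not None else 20 * L,
        n_nucleation=(cfg.n_nucleation if cfg.n_nucleation is not None
                      else 50 * L),
        n_finalization=(cfg.n_finalization if cfg.n_finalization is not None
                        else 30 * L),
    )


@dataclass
class TrajectorySnapshot:
    stage: str
    iteration: int
    torsions: TorsionChain
    structure: ProteinStructure
    energies: dict
    rg: float


@dataclass
class Trajectory:
    snapshots: list = field(default_factory=list)
    manifest: dict = field(default_factory=dict)

    @property
    def final(self) -> ProteinStructure:
        return self.snapshots[-1].structure

    def stage_snapshots(self, stage: str):
        return [s for s in self.snapshots if s.stage == stage]

    def write_pdb(self, path):
        write_structure(path, [s.structure for s in self.snapshots])

    def write_csv(self, path):
        import pandas as pd
        rows = []
        for s in self.snapshots:
            row = {"stage": s.stage, "iteration": s.iteration, "rg": s.rg}
            row.update(s.energies)
            rows.append(row)
        pd.DataFrame(rows).to_csv(path, index=False)

    def write_manifest(self, path):
        with open(path, "w") as fh:
            json.dump(self.manifest, fh, indent=2, sort_keys=True)


def metropolis_accept(delta_e: float, kT: float, rng) -> bool:
    """Accept downhill moves always, uphill with probability
    exp(-delta_e / kT).  Always consumes exactly one uniform draw so that
    acceptance decisions stay aligned across replayed streams."""
    if kT <= 0:
        raise ValueError("kT must be positive")
    u = rng.random()
    if delta_e <= 0:
        return True
    return u < np.exp(-delta_e / kT)


def extended_chain(sequence: str, structure_id: str = "extended"
                   ) -> ProteinStructure:
    L = len(sequence)
    t = TorsionChain(np.full(L, EXTENDED_PHI), np.full(L, EXTENDED_PSI),
                     np.full(L, EXTENDED_OMEGA), sequence)
    return rebuild_cartesian(t, sequence, structure_id)


def _apply_fragment(torsions: TorsionChain, frag) -> TorsionChain:
    t = torsions.copy()
    s = frag.target_start
    t.phi[s:s + frag.length] = frag.torsions[:, 0]
    t.psi[s:s + frag.length] = frag.torsions[:, 1]
    t.omega[s:s + frag.length] = frag.torsions[:, 2]
    # the first residue's phi/omega are not realized; keep them NaN-safe
    return t


def _snapshot(stage, iteration, torsions, structure, energies):
    return TrajectorySnapshot(stage, iteration, torsions.copy(), structure,
                              dict(energies), radius_of_gyration(structure))


def initialize_stage(sequence: str, lib: FragmentLibrary,
                     weights: EnergyWeights, config: SamplerConfig, rng):
    """Stage 1: random 3-mer assembly from the extended chain.

    Exactly n_init (default 20·L) trials, each scored by the stage-1
    physical potential with Metropolis acceptance at kT_physi.
    """
    L = len(sequence)
    cfg = config.resolve(L)
    torsions = TorsionChain(np.full(L, EXTENDED_PHI),
                            np.full(L, EXTENDED_PSI),
                            np.full(L, EXTENDED_OMEGA), sequence)
    current = rebuild_cartesian(torsions, sequence, "conf")
    e_cur = physical_energy(current, 1, weights)
    kT = cfg.kT_physi
    snapshots = [_snapshot("init", 0, torsions, current,
                           {"e_physi1": e_cur.total})]
    for it in range(1, cfg.n_init + 1):
        frag = sample_fragment(lib, 3, rng)
        trial_t = _apply_fragment(torsions, frag)
        trial = rebuild_cartesian(trial_t, sequence, "conf")
        e_try = physical_energy(trial, 1, weights)
        if metropolis_accept(e_try.total - e_cur.total, kT, rng):
            torsions, current, e_cur = trial_t, trial, e_try
        kT = max(kT * cfg.cooling, 1e-6)
        if it % cfg.stride == 0 or it == cfg.n_init:
            snapshots.append(_snapshot("init", it, torsions, current,
                                       {"e_physi1": e_cur.total}))
    return torsions, current, snapshots


def _dual_stage(stage_name, torsions, current, lib, restraints, weights,
                cfg, rng, n_iter, weighted_stat, accept_rule):
    """Shared nucleation/finalization loop: 6-mers then 3-mers, dual-score
    acceptance per ``accept_rule``."""
    sequence = torsions.sequence
    e_phys = physical_energy(current, 2, weights).total
    e_stat = statistical_energy(current, restraints, weighted=weighted_stat)
    kT_p, kT_s = cfg.kT_physi, cfg.kT_stati
    snapshots = []
    n_accept = 0
    for it in range(1, n_iter + 1):
        length = 6 if it <= n_iter // 2 else 3
        try:
            frag = sample_fragment(lib, length, rng)
        except Exception:
            frag = sample_fragment(lib, 3, rng)
        trial_t = _apply_fragment(torsions, frag)
        trial = rebuild_cartesian(trial_t, sequence, "conf")
        t_phys = physical_energy(trial, 2, weights).total
        t_stat = statistical_energy(trial, restraints, weighted=weighted_stat)
        if accept_rule(t_stat - e_stat, t_phys - e_phys, kT_s, kT_p, rng):
            torsions, current = trial_t, trial
            e_phys, e_stat = t_phys, t_stat
            n_accept += 1
        kT_p = max(kT_p * cfg.cooling, 1e-6)
        kT_s = max(kT_s * cfg.cooling, 1e-6)
        if it % cfg.stride == 0 or it == n_iter:
            snapshots.append(_snapshot(
                stage_name, it, torsions, current,
                {"e_physi2": e_phys, "e_stati": e_stat}))
    return torsions, current, snapshots, n_accept


def _accept_and(d_stat, d_phys, kT_s, kT_p, rng):
    ok_s = metropolis_accept(d_stat, kT_s, rng)
    ok_p = metropolis_accept(d_phys, kT_p, rng)
    return ok_s and ok_p


def _accept_or(d_stat, d_phys, kT_s, kT_p, rng):
    if metropolis_accept(d_stat, kT_s, rng):
        return True
    return metropolis_accept(d_phys, kT_p, rng)


def nucleation_stage(torsions, current, lib, restraints: RestraintMap,
                     weights, config: SamplerConfig, rng):
    """Stage 2: conformational replacement requires BOTH the weighted
    statistical Metropolis test (kT_stati) and the stage-2 physical test
    (kT_physi) to pass."""
    cfg = config.resolve(len(torsions))
    return _dual_stage("nucleation", torsions, current, lib, restraints,
                       weights, cfg, rng, cfg.n_nucleation,
                       weighted_stat=True, accept_rule=_accept_and)


def finalization_stage(torsions, current, lib, restraints: RestraintMap,
                       weights, config: SamplerConfig, rng):
    """Stage 3: greedy acceptance — the unweighted statistical test is
    tried first and the physical test serves as a fallback."""
    cfg = config.resolve(len(torsions))
    return _dual_stage("finalization", torsions, current, lib, restraints,
                       weights, cfg, rng, cfg.n_finalization,
                       weighted_stat=False, accept_rule=_accept_or)


def run_pipeline(target_model: ProteinStructure, msta: MSTA,
                 config: SamplerConfig = None,
                 weights: EnergyWeights = None) -> Trajectory:
    """Full chain: conservation profile -> restraints -> fragment library
    -> three sampling stages.  Returns the ordered snapshot stream plus a
    manifest sufficient for bit-exact replay."""
    if config is None:
        config = SamplerConfig()
    if weights is None:
        weights = EnergyWeights()
    L = len(target_model)
    cfg = config.resolve(L)
    rng = np.random.default_rng(cfg.seed)

    f = residue_frequency_scores(msta)
    restraints = restraint_map(target_model, f, epsilon=cfg.epsilon,
                               min_separation=cfg.min_separation)
    lib = build_library(msta, f)

    sequence = target_model.sequence
    torsions, current, snaps1 = initialize_stage(sequence, lib, weights,
                                                 cfg, rng)
    torsions, current, snaps2, acc2 = nucleation_stage(
        torsions, current, lib, restraints, weights, cfg, rng)
    torsions, current, snaps3, acc3 = finalization_stage(
        torsions, current, lib, restraints, weights, cfg, rng)

    manifest = {
        "seed": cfg.seed,
        "target_id": target_model.id,
        "length": L,
        "n_homologs": msta.n,
        "lambda_threshold": msta.lambda_threshold,
        "m_removed": lib.m_removed,
        "n_fragments_3": lib.n_fragments(3),
        "n_fragments_6": lib.n_fragments(6),
        "config": {k: v for k, v in asdict(cfg).items()},
        "accepted_nucleation": acc2,
        "accepted_finalization": acc3,
        "min_f": float(np.min(f.f)),
        "mean_f": float(np.mean(f.f)),
    }
    traj = Trajectory(snaps1 + snaps2 + snaps3, manifest)
    traj.f_profile = f
    traj.restraints = restraints
    traj.library = lib
    return traj
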