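"""Shared fixtures: ideal chains, the two-region synthetic family, and a
small pool of random toy structures for oracle comparisons."""

import numpy as np
import pytest

import foldpath as fp
from foldpath.structio import TorsionChain, rebuild_cartesian
from foldpath.synthdata import Region, EnsembleSpec, make_homologs


def build_chain(phi, psi, sequence=None, omega=180.0):
    """Uniform-torsion chain helper."""
    L = max(np.size(phi), np.size(psi))
    if sequence is None:
        sequence = "A" * L
    L = len(sequence)
    t = TorsionChain(np.full(L, phi), np.full(L, psi), np.full(L, omega),
                     sequence)
    return rebuild_cartesian(t, sequence)


def ideal_helix(L=20, sequence=None):
    return build_chain(-57.0, -47.0, sequence or "A" * L)


def extended_chain(L=20, sequence=None):
    return build_chain(-139.0, 135.0, sequence or "A" * L)


def random_chain(L, rng, compact=True):
    """Random-torsion toy chain; ``compact`` biases toward folded basins."""
    if compact:
        phi = rng.uniform(-160.0, -50.0, L)
        psi = rng.uniform(-60.0, 160.0, L)
    else:
        phi = rng.uniform(-180.0, 180.0, L)
        psi = rng.uniform(-180.0, 180.0, L)
    t = TorsionChain(phi, psi, np.full(L, 180.0), "A" * L)
    return rebuild_cartesian(t, "A" * L)


@pytest.fixture(scope="session")
def mixed_native():
    """The two-region benchmark native: helix-rich conserved half,
    strand/coil variable half."""
    return fp.make_native(fp.BLUEPRINTS["mixed"], seed=1)


@pytest.fixture(scope="session")
def two_region_case(mixed_native):
    """One seeded realization of the conserved/variable homolog family
    (sigma 0.5 vs 3.0 A, 20 homologs, 2 decoys) with its filtered MSTA."""
    native = mixed_native
    L = len(native)
    split = L // 2
    regions = [Region("conserved", 0, split, 0.5),
               Region("variable", split, L, 3.0)]
    spec = EnsembleSpec(fp.BLUEPRINTS["mixed"], regions,
                        n_homologs=20, n_decoys=2, seed=0)
    structures, aligned = make_homologs(native, spec)
    msta = fp.build_msta(native, aligned, 0.3)
    return {"native": native, "split": split, "regions": regions,
            "structures": structures, "aligned": aligned, "msta": msta}


@pytest.fixture(scope="session")
def identical_msta(mixed_native):
    """MSTA of exact copies of the native (the sigma = 0 limit)."""
    from foldpath.msta import AlignedHomolog, _superpose_and_deviations
    native = mixed_native
    L = len(native)
    mapping = np.stack([np.arange(L)] * 2, axis=1)
    homs = []
    for k in range(5):
        s = native.copy()
        s.id = f"copy{k}"
        tm, dev = _superpose_and_deviations(native, s, mapping)
        homs.append(AlignedHomolog(s, mapping.copy(), tm, dev))
    return fp.build_msta(native, homs, 0.3)
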