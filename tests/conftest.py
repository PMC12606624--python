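import numpy as np
import pytest

from saxsens.ensemble import MARTINI_LIKE_SCHEME, AtomEnsemble
from saxsens.synthetic import SyntheticSpec, generate_two_domain_ensemble


@pytest.fixture(scope="session")
def small_spec():
    return SyntheticSpec(n_core_beads=20, n_arm_beads=12, n_frames=40, seed=7)


@pytest.fixture(scope="session")
def small_ensemble(small_spec):
    """A small two-state bead ensemble with state labels (session-cached)."""
    return generate_two_domain_ensemble(small_spec)


def make_toy_protein(res_types=None, seed=0, spread=1.2, spacing=5.0):
    """A compact single-frame atomistic toy: residues on a lattice, heavy
    atoms (names from the coarse-graining table) jittered around each
    residue center."""
    rng = np.random.default_rng(seed)
    res_types = res_types or ["ALA", "GLY", "TRP", "LYS", "PHE", "SER",
                              "GLU", "VAL", "LEU", "ASN"] * 2
    axes = np.arange(-2, 3) * spacing
    centers = np.stack(np.meshgrid(axes, axes, axes, indexing="ij"), -1).reshape(-1, 3)
    centers = centers[np.argsort(np.linalg.norm(centers, axis=1))][:len(res_types)]
    names, els, rids, rnames, coords = [], [], [], [], []
    for i, (rt, c) in enumerate(zip(res_types, centers)):
        atoms = sorted({a for grp in MARTINI_LIKE_SCHEME[rt] for a in grp})
        for a in atoms:
            names.append(a)
            els.append(a[0])
            rids.append(i + 1)
            rnames.append(rt)
            coords.append(c + rng.normal(0, spread, 3))
    return AtomEnsemble(
        coords=np.array(coords)[None], elements=np.array(els),
        atom_names=np.array(names), residue_ids=np.array(rids),
        residue_names=np.array(rnames),
        chain_ids=np.array(["A"] * len(names)), masses=np.ones(len(names)))


@pytest.fixture(scope="session")
def toy_protein():
    return make_toy_protein()


def random_rigid_motion(rng):
    """A random rotation matrix and translation vector."""
    from scipy.spatial.transform import Rotation
    return Rotation.random(rng=rng).as_matrix(), rng.normal(0, 20, 3)
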