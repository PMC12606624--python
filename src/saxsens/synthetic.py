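"""Synthetic two-state benchmark with known ground truth.

Emulates the statistical structure of an ensemble-refinement study of a
two-domain protein: a rigid compact core plus a flexible arm that samples
compact (arm folded against the core) and extended (arm pointing away)
states, a target SAXS curve generated from ground-truth state populations
with Gaussian noise, an enhanced-sampling-style bias that concentrates the
prior on the compact state, and cross-links satisfied preferentially in
compact frames. Everything is deterministic under a fixed seed.

Default populations make the recovery problem meaningful: the prior holds
1% extended mass while the truth is 65% extended, so reweighting must move
most of the probability across states.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .ensemble import AtomEnsemble
from .forward import SaxsCurve, default_q_grid, debye_spectrum, ensemble_spectrum
from .formfactors import BeadFormFactor, FormFactorTable
from .maxent import KT_300K, prior_weights

__all__ = [
    "SyntheticSpec",
    "generate_two_domain_ensemble",
    "two_domain_spectra",
    "ground_truth_target",
    "true_weights",
    "synthetic_bias",
    "synthetic_crosslinks",
]


@dataclasses.dataclass
class SyntheticSpec:
    """Parameters of the synthetic two-state benchmark."""

    n_core_beads: int = 30
    n_arm_beads: int = 20
    n_frames: int = 300
    true_fraction_extended: float = 0.65
    prior_fraction_extended: float = 0.01
    noise_level: float = 0.02
    seed: int = 0
    bond_length: float = 3.8   # Å between consecutive arm beads
    clash_distance: float = 3.0  # Å minimum bead separation

    def __post_init__(self):
        for frac in (self.true_fraction_extended, self.prior_fraction_extended):
            if not 0.0 < frac < 1.0:
                raise ValueError("state fractions must lie in (0, 1)")
        if min(self.n_core_beads, self.n_arm_beads, self.n_frames) < 1:
            raise ValueError("counts must be >= 1")
        if self.noise_level <= 0:
            raise ValueError("noise_level must be positive")


def _core_positions(spec: SyntheticSpec) -> np.ndarray:
    """Compact rigid core: the n closest points of a cubic lattice to the
    origin (spacing = bond length), a roughly spherical dense cluster."""
    a = spec.bond_length
    k = 1
    while (2 * k + 1) ** 3 < spec.n_core_beads:
        k += 1
    axes = np.arange(-k, k + 1) * a
    grid = np.stack(np.meshgrid(axes, axes, axes, indexing="ij"), -1).reshape(-1, 3)
    order = np.argsort(np.linalg.norm(grid, axis=1), kind="stable")
    core = grid[order[:spec.n_core_beads]]
    return core - core.mean(axis=0)


def _grow_arm(rng: np.random.Generator, placed: np.ndarray, start: np.ndarray,
              spec: SyntheticSpec, extended: bool, r_fold: float) -> np.ndarray:
    """Self-avoiding random walk for the arm.

    Compact frames keep every arm bead inside a shell of radius ``r_fold``
    around the core center (arm folded against the core); extended frames
    use a persistent outward walk. Steps clashing with any placed bead are
    rejected and retried; if the walk jams, it restarts; persistent failure
    raises.
    """
    outward = start / np.linalg.norm(start)
    for _restart in range(50):
        arm = []
        occupied = placed
        pos = start
        direction = outward.copy()
        ok = True
        for _b in range(spec.n_arm_beads):
            for _try in range(300):
                if extended:
                    step = direction + 0.45 * rng.standard_normal(3)
                else:
                    step = rng.standard_normal(3)
                step /= np.linalg.norm(step)
                cand = pos + spec.bond_length * step
                if not extended and np.linalg.norm(cand) > r_fold:
                    continue
                d = np.linalg.norm(occupied - cand, axis=1)
                if len(arm):
                    d = np.concatenate([d, np.linalg.norm(np.array(arm) - cand, axis=1)])
                if (d < spec.clash_distance).any():
                    continue
                if extended:
                    direction = 0.75 * direction + 0.25 * step
                    direction /= np.linalg.norm(direction)
                pos = cand
                arm.append(cand)
                break
            else:
                ok = False
                break
        if ok:
            return np.array(arm)
    raise RuntimeError(
        "arm generation failed: self-avoiding walk cannot place beads; "
        "loosen clash_distance or reduce n_arm_beads")


def generate_two_domain_ensemble(spec: SyntheticSpec):
    """Generate the two-domain bead ensemble and per-frame state labels.

    Returns ``(ensemble, labels)`` where labels is a boolean array, True
    for extended frames. States are sampled 50/50 so that both are well
    represented regardless of the prior/true populations (which are
    carried by weights, not frame counts). The core (chain A) is rigid and
    identical across frames; the arm (chain B) is a fresh self-avoiding
    walk per frame. Beads are exposed as Cα-like pseudo-atoms so the whole
    downstream pipeline (selection, Rg, SAXS, contacts) applies unchanged.
    """
    rng = np.random.default_rng(spec.seed)
    core = _core_positions(spec)
    r_core = np.linalg.norm(core, axis=1).max()
    attach = core[np.argmax(core[:, 0])]
    start = attach + spec.bond_length * np.array([1.0, 0.0, 0.0])

    labels = np.zeros(spec.n_frames, dtype=bool)
    labels[rng.random(spec.n_frames) < 0.5] = True
    if spec.n_frames >= 2:  # both states must exist
        labels[0] = False
        labels[-1] = True

    n_beads = spec.n_core_beads + spec.n_arm_beads
    coords = np.empty((spec.n_frames, n_beads, 3))
    for f in range(spec.n_frames):
        # the fold radius varies per compact frame so the compact state has
        # conformational breadth comparable to the extended one
        r_fold_f = r_core + rng.uniform(1.2, 4.0) * spec.bond_length
        arm = _grow_arm(rng, np.vstack([core, start[None]]), start, spec,
                        extended=bool(labels[f]), r_fold=r_fold_f)
        frame = np.vstack([core, arm])
        coords[f] = frame

    chain_ids = np.array(["A"] * spec.n_core_beads + ["B"] * spec.n_arm_beads)
    residue_ids = np.concatenate([np.arange(1, spec.n_core_beads + 1),
                                  np.arange(1, spec.n_arm_beads + 1)])
    ens = AtomEnsemble(
        coords=coords,
        elements=np.full(n_beads, "C"),
        atom_names=np.full(n_beads, "CA"),
        residue_ids=residue_ids,
        residue_names=np.full(n_beads, "ALA"),
        chain_ids=chain_ids,
        masses=np.full(n_beads, 110.0))
    return ens, labels


def _bead_table() -> FormFactorTable:
    # one average-residue bead kind: ~60 electrons, residue-scale damping
    return FormFactorTable({"ALA": BeadFormFactor(f0=60.0, rg=2.7)})


def two_domain_spectra(ens: AtomEnsemble, q: np.ndarray | None = None) -> np.ndarray:
    """Per-frame Debye intensities of the synthetic bead ensemble."""
    q = default_q_grid() if q is None else np.asarray(q, dtype=float)
    table = _bead_table()
    return np.stack([
        debye_spectrum(ens.coords[f], ens.residue_names, table, q).intensity
        for f in range(ens.n_frames)])


def true_weights(labels: np.ndarray, spec: SyntheticSpec) -> np.ndarray:
    """Ground-truth frame weights: ``true_fraction_extended`` mass spread
    uniformly over extended frames, the rest over compact frames."""
    labels = np.asarray(labels, dtype=bool)
    w = np.empty(len(labels))
    n_ext = labels.sum()
    n_comp = len(labels) - n_ext
    w[labels] = spec.true_fraction_extended / n_ext
    w[~labels] = (1.0 - spec.true_fraction_extended) / n_comp
    return w


def ground_truth_target(ens: AtomEnsemble, labels: np.ndarray,
                        spec: SyntheticSpec,
                        q: np.ndarray | None = None,
                        s_matrix: np.ndarray | None = None):
    """Noisy target SAXS curve from the ground-truth weighted ensemble.

    The noiseless curve is the true-weighted ensemble spectrum; Gaussian
    noise with sd = noise_level · I(q) is added and the same sd is reported
    as the curve's standard error. Returns ``(target, w_true)``. The
    default grid has experiment-like density (101 points on (0, 0.30]);
    measured curves carry hundreds of q points, and the reweighting stage
    consumes the full curve, not the sparse steering grid.
    """
    q = default_q_grid(101, 0.30) if q is None else np.asarray(q, dtype=float)
    if s_matrix is None:
        s_matrix = two_domain_spectra(ens, q)
    w_true = true_weights(labels, spec)
    clean = ensemble_spectrum(s_matrix, w_true, q)
    rng = np.random.default_rng(spec.seed + 1)
    sd = spec.noise_level * clean.intensity
    noisy = clean.intensity + rng.normal(0.0, sd)
    return SaxsCurve(q=q, intensity=noisy, se=sd), w_true


def synthetic_bias(labels: np.ndarray, spec: SyntheticSpec,
                   kT: float = KT_300K) -> np.ndarray:
    """Two-level bias whose Boltzmann prior puts ``prior_fraction_extended``
    mass on the extended frames (closed form, exact by construction)."""
    labels = np.asarray(labels, dtype=bool)
    n_ext = int(labels.sum())
    n_comp = len(labels) - n_ext
    p = spec.prior_fraction_extended
    v_ext = kT * np.log(p * n_comp / ((1.0 - p) * n_ext))
    bias = np.zeros(len(labels))
    bias[labels] = v_ext
    # sanity: prior_weights(bias) reproduces p exactly
    assert abs(prior_weights(bias, kT)[labels].sum() - p) < 1e-9
    return bias


def synthetic_crosslinks(ens: AtomEnsemble, labels: np.ndarray,
                         n_links: int = 4,
                         window: tuple[float, float] = (10.0, 35.0),
                         seed: int = 0) -> pd.DataFrame:
    """Emit core–arm cross-links satisfied preferentially in compact frames.

    Candidate pairs (core bead, arm bead) must fall inside ``window`` in
    ≥ 90% of compact frames and outside it in ≥ 50% of extended frames;
    the best ``n_links`` by compact compliance are emitted with synthetic
    spectral scores > 30 so the default loader keeps them all.
    """
    if n_links < 1:
        raise ValueError("n_links must be >= 1")
    labels = np.asarray(labels, dtype=bool)
    core_idx = np.nonzero(ens.chain_ids == "A")[0]
    arm_idx = np.nonzero(ens.chain_ids == "B")[0]
    lo, hi = window

    d = np.linalg.norm(ens.coords[:, core_idx, None, :]
                       - ens.coords[:, None, arm_idx, :], axis=3)
    inside = (d >= lo) & (d <= hi)
    rate_compact = inside[~labels].mean(axis=0)
    rate_ext_out = 1.0 - inside[labels].mean(axis=0)
    qualifies = (rate_compact >= 0.90) & (rate_ext_out >= 0.50)
    if qualifies.sum() < n_links:
        raise ValueError(
            f"only {int(qualifies.sum())} core-arm pairs qualify "
            f"(need {n_links}); try a larger window")

    score_fn = np.where(qualifies, rate_compact + rate_ext_out, -np.inf)
    flat = np.argsort(score_fn, axis=None, kind="stable")[::-1][:n_links]
    ci, ai = np.unravel_index(flat, score_fn.shape)

    rng = np.random.default_rng(seed)
    rows = []
    for c, a in zip(ci, ai):
        rows.append({
            "protein_a": "CORE", "res_a": int(ens.residue_ids[core_idx[c]]),
            "protein_b": "ARM", "res_b": int(ens.residue_ids[arm_idx[a]]),
            "score": float(np.round(rng.uniform(31.0, 60.0), 2)),
            "kind": "inter"})
    return pd.DataFrame(rows)
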