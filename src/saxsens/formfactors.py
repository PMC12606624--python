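"""Scattering form factors for atoms and coarse-grained beads.

Atomic factors use the standard four-Gaussian-plus-constant parametrization

    f(q) = sum_k a_k exp(-b_k (q / 4π)^2) + c

with the tabulated Cromer–Mann coefficients for the elements occurring in
proteins. Bead (pseudo-atom) factors default to the q = 0 sum of the
constituent atomic factors damped by a Gaussian of the bead radius of
gyration — a declared approximation with pluggable tables, not a published
coarse-grained parametrization. The solvated bead factor adds a
solvent-layer term proportional to the bead's solvent exposure:

    F(q) = F_vac(q) + contrast · exposure · F_w(q)

where F_w is the water-molecule form factor.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping

import numpy as np

__all__ = [
    "GaussianFormFactor",
    "BeadFormFactor",
    "FormFactorTable",
    "atomic_table",
    "water_form_factor",
    "solvated_bead_factor",
]

# Cromer–Mann coefficients (a1..a4, b1..b4, c), International Tables vol. C.
_CROMER_MANN = {
    "H": ([0.489918, 0.262003, 0.196767, 0.049879],
          [20.6593, 7.74039, 49.5519, 2.20159], 0.001305),
    "C": ([2.31000, 1.02000, 1.58860, 0.865000],
          [20.8439, 10.2075, 0.568700, 51.6512], 0.215600),
    "N": ([12.2126, 3.13220, 2.01250, 1.16630],
          [0.005700, 9.89330, 28.9975, 0.582600], -11.529),
    "O": ([3.04850, 2.28680, 1.54630, 0.867000],
          [13.2771, 5.70110, 0.323900, 32.9089], 0.250800),
    "S": ([6.90530, 5.20340, 1.43790, 1.58630],
          [1.46790, 22.2151, 0.253600, 56.1720], 0.866900),
    "P": ([6.43450, 4.17910, 1.78000, 1.49080],
          [1.90670, 27.1570, 0.526000, 68.1645], 1.11490),
}


@dataclasses.dataclass(frozen=True)
class GaussianFormFactor:
    """Four-Gaussian + constant atomic form factor."""

    a: tuple
    b: tuple
    c: float

    def __call__(self, q: np.ndarray) -> np.ndarray:
        q = np.asarray(q, dtype=float)
        s2 = (q / (4.0 * np.pi)) ** 2
        a = np.asarray(self.a)
        b = np.asarray(self.b)
        return np.exp(-np.multiply.outer(s2, b)) @ a + self.c


@dataclasses.dataclass(frozen=True)
class BeadFormFactor:
    """Gaussian-damped bead form factor: f(q) = f0 · exp(-(q·rg)²/2)."""

    f0: float
    rg: float

    def __call__(self, q: np.ndarray) -> np.ndarray:
        q = np.asarray(q, dtype=float)
        return self.f0 * np.exp(-0.5 * (q * self.rg) ** 2)


class FormFactorTable:
    """Maps particle kinds to form-factor functions.

    Every kind must have f(0) > 0. ``__call__(kinds, q)`` evaluates the
    table for an array of per-particle kinds, returning (n_particles, n_q).
    """

    def __init__(self, factors: Mapping[str, object]):
        self._factors = dict(factors)
        for kind, f in self._factors.items():
            if float(np.atleast_1d(f(np.array([0.0])))[0]) <= 0:
                raise ValueError(f"form factor for kind {kind!r} has f(0) <= 0")

    def __contains__(self, kind) -> bool:
        return str(kind) in self._factors

    def __getitem__(self, kind):
        try:
            return self._factors[str(kind)]
        except KeyError:
            raise KeyError(f"kind {kind!r} missing from form-factor table") from None

    def kinds(self):
        return list(self._factors)

    def __call__(self, kinds, q: np.ndarray) -> np.ndarray:
        q = np.asarray(q, dtype=float)
        kinds = np.asarray(kinds)
        uniq, inv = np.unique(kinds, return_inverse=True)
        vals = np.stack([np.atleast_1d(self[k](q)) for k in uniq])
        return vals[inv]


def atomic_table(fold_hydrogens: bool = False) -> FormFactorTable:
    """Form-factor table for protein elements.

    With ``fold_hydrogens`` the average hydrogen complement of a protein
    heavy atom is folded into its factor (useful for hydrogen-stripped
    inputs): C gains 1.5 H, N gains 1 H, O gains 0.5 H on average.
    """
    base = {el: GaussianFormFactor(tuple(a), tuple(b), c)
            for el, (a, b, c) in _CROMER_MANN.items()}
    if not fold_hydrogens:
        return FormFactorTable(base)

    h = base["H"]
    n_h = {"C": 1.5, "N": 1.0, "O": 0.5, "S": 0.0, "P": 0.0}

    class _Folded:
        def __init__(self, f, nh):
            self.f, self.nh = f, nh

        def __call__(self, q):
            return self.f(q) + self.nh * h(q)

    out = {el: _Folded(f, n_h.get(el, 0.0)) for el, f in base.items()}
    return FormFactorTable(out)


_WATER = None


def water_form_factor(q: np.ndarray) -> np.ndarray:
    """Form factor of a water molecule, F_w(q) = f_O(q) + 2 f_H(q)."""
    global _WATER
    if _WATER is None:
        tab = atomic_table()
        _WATER = (tab["O"], tab["H"])
    f_o, f_h = _WATER
    return f_o(q) + 2.0 * f_h(q)


def solvated_bead_factor(vacuum_factor, exposure: float, q: np.ndarray,
                         contrast: float) -> np.ndarray:
    """Bead scattering factor with the solvent-layer contribution.

    F(q) = F_vac(q) + contrast · exposure · F_w(q). ``contrast`` = 0 or
    ``exposure`` = 0 reduce exactly to the vacuum factor.
    """
    if not 0.0 <= exposure <= 1.0:
        raise ValueError(f"exposure {exposure} outside [0, 1]")
    q = np.asarray(q, dtype=float)
    f_vac = vacuum_factor(q) if callable(vacuum_factor) else np.asarray(vacuum_factor)
    return f_vac + contrast * exposure * water_form_factor(q)


def bead_table_from_structure(ens, beads, fold_hydrogens: bool = False,
                              frame: int = 0) -> FormFactorTable:
    """Derive bead vacuum factors from the beads' constituent atoms.

    Each bead kind gets a Gaussian-damped factor whose amplitude is the
    q = 0 sum of the constituent atomic factors and whose damping length is
    the bead's internal radius of gyration (f(0)-weighted atom spread,
    measured on ``frame``), averaged over the beads of that kind. A
    single-atom bead has zero internal extent and hence no damping. This
    is a declared approximation, not a published coarse-grained
    parametrization; tables remain pluggable.
    """
    if beads.members is None:
        raise ValueError("bead ensemble lacks member atom indices")
    atoms = atomic_table(fold_hydrogens=fold_hydrogens)
    f0_by_el = {el: float(atoms[el](np.array([0.0]))[0])
                for el in np.unique(ens.elements)}
    sums: dict[str, list] = {}
    for b, idx in enumerate(beads.members):
        f0s = np.array([f0_by_el[e] for e in ens.elements[idx]])
        total = f0s.sum()
        center = (f0s[:, None] * ens.coords[frame, idx]).sum(0) / total
        rg2 = (f0s * ((ens.coords[frame, idx] - center) ** 2).sum(1)).sum() / total
        sums.setdefault(str(beads.bead_kind[b]), []).append((total, np.sqrt(rg2)))
    return FormFactorTable({
        kind: BeadFormFactor(f0=float(np.mean([v[0] for v in vals])),
                             rg=float(np.mean([v[1] for v in vals])))
        for kind, vals in sums.items()})


def default_bead_table(kinds, f0: float = 60.0, rg: float = 2.7) -> FormFactorTable:
    """A uniform bead table: every kind gets the same Gaussian-damped factor.

    f0 defaults to the electron count of an average amino-acid residue
    (~60 e) and rg to a typical residue radius of gyration (2.7 Å).
    """
    ff = BeadFormFactor(f0=f0, rg=rg)
    return FormFactorTable({str(k): ff for k in np.unique(np.asarray(kinds))})
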