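"""SAXS forward model: Debye scattering, ensemble averaging, curve handling.

The scattered intensity of one structure is the exact orientationally
averaged double sum over particles (Debye equation)

    I(q) = Σ_i Σ_j f_i(q) f_j(q) sin(q r_ij) / (q r_ij)

with sinc(0) = 1 covering the self terms and the q → 0 limit. The same
expression applies to coarse-grained beads with their (optionally
solvent-corrected) scattering factors.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
from scipy.spatial.distance import pdist

from .formfactors import FormFactorTable, solvated_bead_factor

__all__ = [
    "SaxsCurve",
    "default_q_grid",
    "debye_spectrum",
    "frame_spectra",
    "bead_frame_spectra",
    "ensemble_spectrum",
    "smooth_experimental",
    "resample_curve",
    "fit_scale",
    "read_dat",
    "write_dat",
]


@dataclasses.dataclass
class SaxsCurve:
    """A SAXS curve: q grid (Å⁻¹), intensities, optional standard errors."""

    q: np.ndarray
    intensity: np.ndarray
    se: np.ndarray | None = None

    def __post_init__(self):
        self.q = np.asarray(self.q, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.q.ndim != 1 or self.intensity.shape != self.q.shape:
            raise ValueError("q and intensity must be 1-D and equal length")
        if (np.diff(self.q) <= 0).any():
            raise ValueError("q must be strictly increasing")
        if (self.q < 0).any():
            raise ValueError("q must be non-negative")
        if not np.isfinite(self.intensity).all():
            raise ValueError("intensity must be finite")
        if self.intensity[0] <= 0:
            raise ValueError("intensity at min(q) must be positive")
        if self.se is not None:
            self.se = np.asarray(self.se, dtype=float)
            if self.se.shape != self.q.shape or (self.se <= 0).any():
                raise ValueError("se must be positive and match q")

    def __len__(self) -> int:
        return len(self.q)


def default_q_grid(n_points: int = 19, q_max: float = 0.30) -> np.ndarray:
    """Uniform grid of ``n_points`` on (0, q_max] Å⁻¹ (q = 0 excluded)."""
    return np.linspace(q_max / n_points, q_max, n_points)


def _sinc(x: np.ndarray) -> np.ndarray:
    # np.sinc is sin(pi x)/(pi x); we need sin(x)/x with sinc(0)=1
    return np.sinc(x / np.pi)


def debye_spectrum(coords: np.ndarray, kinds, table: FormFactorTable,
                   q: np.ndarray) -> SaxsCurve:
    """Exact Debye double-sum intensity of one frame.

    ``coords`` is (n_particles, 3) in Å; ``kinds`` indexes into ``table``.
    Evaluated as I(q) = Σ_i f_i² + 2 Σ_{i<j} f_i f_j sinc(q r_ij).
    """
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 2 or coords.shape[0] < 1:
        raise ValueError("coords must be (n_particles, 3) with >= 1 particle")
    q = np.asarray(q, dtype=float)
    if (q < 0).any():
        raise ValueError("q must be non-negative")
    f = table(kinds, q)                      # (n, n_q)
    self_term = (f ** 2).sum(axis=0)
    if coords.shape[0] == 1:
        return SaxsCurve(q=q, intensity=self_term)
    r = pdist(coords)                        # (n_pairs,)
    iu, ju = np.triu_indices(coords.shape[0], k=1)
    cross = f[iu] * f[ju]                    # (n_pairs, n_q)
    sinc = _sinc(np.multiply.outer(r, q))    # (n_pairs, n_q)
    intensity = self_term + 2.0 * (cross * sinc).sum(axis=0)
    return SaxsCurve(q=q, intensity=intensity)


def frame_spectra(coords: np.ndarray, kinds, table: FormFactorTable,
                  q: np.ndarray) -> np.ndarray:
    """Per-frame Debye intensities for an ensemble, shape (n_frames, n_q)."""
    return np.stack([debye_spectrum(c, kinds, table, q).intensity
                     for c in np.asarray(coords, dtype=float)])


def bead_frame_spectra(bead_ens, table: FormFactorTable, q: np.ndarray,
                       contrast: float = 0.0) -> np.ndarray:
    """Per-frame bead spectra with the solvent-layer correction.

    Each bead's factor is F_vac + contrast · exposure · F_w; contrast = 0
    reproduces the vacuum bead spectra exactly.
    """
    q = np.asarray(q, dtype=float)
    factors = np.stack([
        solvated_bead_factor(table[k], float(e), q, contrast)
        for k, e in zip(bead_ens.bead_kind, bead_ens.exposure)])

    class _PerBead:
        def __call__(self, kinds, qq):
            return factors

        def __getitem__(self, k):  # pragma: no cover - not used directly
            raise KeyError

    per_bead = _PerBead()
    out = np.empty((bead_ens.n_frames, len(q)))
    for t in range(bead_ens.n_frames):
        out[t] = debye_spectrum(bead_ens.bead_coords[t],
                                np.arange(bead_ens.n_beads), per_bead, q).intensity
    return out


def ensemble_spectrum(intensities: np.ndarray, weights: np.ndarray,
                      q: np.ndarray) -> SaxsCurve:
    """Pointwise weighted mean of per-frame intensities on a shared grid."""
    intensities = np.asarray(intensities, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if intensities.shape[0] != len(weights):
        raise ValueError("weights length must match frame count")
    if intensities.shape[1] != len(q):
        raise ValueError("intensity grid does not match q grid")
    w = weights / weights.sum()
    return SaxsCurve(q=np.asarray(q, dtype=float), intensity=w @ intensities)


def smooth_experimental(curve: SaxsCurve, window: int = 51) -> SaxsCurve:
    """Centered running mean of the intensity (and se) with an odd window.

    Near the edges the window shrinks symmetrically to the available points,
    so the q grid is unchanged and no padding value is invented.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be odd and >= 1")
    half = window // 2
    n = len(curve)

    def running(y):
        out = np.empty(n)
        for i in range(n):
            h = min(half, i, n - 1 - i)
            out[i] = y[i - h:i + h + 1].mean()
        return out

    se = None if curve.se is None else running(curve.se)
    return SaxsCurve(q=curve.q, intensity=running(curve.intensity), se=se)


def resample_curve(curve: SaxsCurve, q_target: np.ndarray) -> SaxsCurve:
    """Linear interpolation of intensity (and se) onto ``q_target``.

    Extrapolation outside the source grid is refused.
    """
    q_target = np.asarray(q_target, dtype=float)
    if q_target.min() < curve.q[0] - 1e-12 or q_target.max() > curve.q[-1] + 1e-12:
        raise ValueError(
            f"q_target [{q_target.min():g}, {q_target.max():g}] extends beyond "
            f"the curve's range [{curve.q[0]:g}, {curve.q[-1]:g}]")
    intensity = np.interp(q_target, curve.q, curve.intensity)
    se = None if curve.se is None else np.interp(q_target, curve.q, curve.se)
    return SaxsCurve(q=q_target, intensity=intensity, se=se)


def fit_scale(calc: SaxsCurve, exp: SaxsCurve) -> float:
    """Closed-form weighted least-squares intensity scale.

    Returns c minimizing Σ_i ((c·I_calc − I_exp) / se_i)²; no additive
    background.
    """
    if len(calc) != len(exp) or not np.allclose(calc.q, exp.q):
        raise ValueError("calc and exp must share the q grid")
    if exp.se is None:
        raise ValueError("exp curve needs standard errors")
    if np.allclose(calc.intensity, 0):
        raise ValueError("calc intensities are all zero")
    w = 1.0 / exp.se ** 2
    return float((w * calc.intensity * exp.intensity).sum()
                 / (w * calc.intensity ** 2).sum())


def read_dat(path: str | Path) -> SaxsCurve:
    """Read a 3-column SAXS text file (q, I, σ); '#' lines are comments.

    The SASBDB .dat dialect (header comments, whitespace-delimited) parses;
    a missing third column yields a curve without errors.
    """
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            try:
                vals = [float(p) for p in parts[:3]]
            except ValueError:
                continue  # tolerate stray header lines, as in SASBDB files
            rows.append(vals)
    if not rows:
        raise ValueError(f"no data rows in {path}")
    ncol = min(len(r) for r in rows)
    arr = np.array([r[:ncol] for r in rows])
    # a zero-filled sigma column (our own writer's placeholder) means "no errors"
    se = arr[:, 2] if ncol >= 3 and (arr[:, 2] > 0).all() else None
    return SaxsCurve(q=arr[:, 0], intensity=arr[:, 1], se=se)


def write_dat(curve: SaxsCurve, path: str | Path, header: str = "") -> None:
    """Write a curve in 3-column text form (q, I, σ)."""
    with open(path, "w") as fh:
        if header:
            for line in header.splitlines():
                fh.write(f"# {line}\n")
        fh.write("# q(1/A)  I(q)  sigma\n")
        se = curve.se if curve.se is not None else np.zeros(len(curve))
        for qi, ii, si in zip(curve.q, curve.intensity, se):
            fh.write(f"{qi:.6e} {ii:.6e} {si:.6e}\n")
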