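"""Maximum-entropy reweighting of a bias-weighted prior ensemble.

Given per-frame observables s_i(x_t) (here SAXS intensities), targets
s_exp, an optional enhanced-sampling bias V_b(x_t) and a regularization
scale σ, the posterior weights are

    w_t ∝ exp( −Σ_i λ_i s_i(x_t) + V_b(x_t)/k_B T )

with the multipliers λ* minimizing the convex dual

    Γ(λ) = ln( (1/N_s) Σ_t exp(−Σ_i λ_i s_i(x_t) + V_b(x_t)/k_B T) )
         + Σ_i λ_i s_i^exp + (1/2) Σ_i λ_i² σ_i² .

The quadratic term models experimental error and acts as a regularizer;
at the minimum the stationarity condition reads
⟨s_i⟩_w − s_i^exp = −λ_i* σ_i², i.e. the fit is allowed to miss each
target by λ_i* σ_i². Diagnostics: Kish effective sample size
K = (Σ w)²/Σ w² and the reduced χ² of the reweighted spectrum.

The API follows the model/results pattern: build a
:class:`MaxEntReweight` from the data, call :meth:`~MaxEntReweight.fit`
(or :meth:`~MaxEntReweight.tune_sigma`), inspect the returned
:class:`ReweightResults`.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import scipy.optimize
from scipy.special import logsumexp

from .forward import SaxsCurve

__all__ = [
    "KT_300K",
    "MaxEntReweight",
    "ReweightResults",
    "prior_weights",
    "kish_size",
    "reduced_chi2",
    "block_bootstrap",
]

#: Thermal energy k_B·T at 300 K in kcal/mol.
KT_300K = 0.0019872041 * 300.0


def prior_weights(bias: np.ndarray | None, kT: float = KT_300K,
                  n_frames: int | None = None) -> np.ndarray:
    """Prior frame weights from a bias potential: w_t ∝ exp(V_b(x_t)/kT).

    Without a bias the prior is uniform (``n_frames`` required). The
    exponential is max-shifted, so adding a constant to all biases leaves
    the weights unchanged and overflow is impossible.
    """
    if kT <= 0:
        raise ValueError("kT must be positive")
    if bias is None:
        if n_frames is None:
            raise ValueError("n_frames required when bias is None")
        return np.full(n_frames, 1.0 / n_frames)
    bias = np.asarray(bias, dtype=float)
    if not np.isfinite(bias).all():
        raise ValueError("bias energies must be finite")
    x = bias / kT
    w = np.exp(x - x.max())
    return w / w.sum()


def kish_size(weights: np.ndarray) -> float:
    """Kish effective sample size K = (Σ w)² / Σ w²; scale-invariant."""
    w = np.asarray(weights, dtype=float)
    if (w < 0).any():
        raise ValueError("weights must be non-negative")
    s = w.sum()
    if s == 0:
        raise ValueError("weights are all zero")
    return float(s ** 2 / (w ** 2).sum())


def reduced_chi2(fit: SaxsCurve, exp: SaxsCurve,
                 se_total: np.ndarray | None = None) -> float:
    """Reduced χ² = (1/(m−1)) Σ_i ((I_fit − I_exp)/SE_i)².

    ``se_total`` should combine experimental and predicted uncertainty in
    quadrature; it defaults to the experimental errors of ``exp``.
    """
    if len(fit) != len(exp) or not np.allclose(fit.q, exp.q):
        raise ValueError("fit and exp must share the q grid")
    m = len(exp)
    if m < 2:
        raise ValueError("need at least 2 points")
    se = np.asarray(se_total, dtype=float) if se_total is not None else exp.se
    if se is None:
        raise ValueError("no standard errors available")
    if (se <= 0).any():
        raise ValueError("standard errors must be positive")
    resid = (fit.intensity - exp.intensity) / se
    return float((resid ** 2).sum() / (m - 1))


@dataclasses.dataclass
class ReweightResults:
    """Outcome of a maximum-entropy reweighting fit."""

    lambdas: np.ndarray
    weights: np.ndarray
    kish: float
    chi2: float | None
    gamma_min: float
    converged: bool
    sigma: np.ndarray
    n_iter: int
    model: "MaxEntReweight"

    def __post_init__(self):
        w = np.asarray(self.weights, dtype=float)
        if (not np.isfinite(w).all() or (w < 0).any()
                or abs(w.sum() - 1.0) > 1e-9):
            raise ValueError("posterior weights must be finite, normalized and >= 0")

    @property
    def reweighted_observables(self) -> np.ndarray:
        """⟨s_i⟩_w under the posterior weights."""
        return self.weights @ self.model.s_matrix

    def summary(self) -> str:
        lines = [
            "Maximum-entropy reweighting",
            "===========================",
            f"frames (N_s):          {self.model.n_frames}",
            f"observables:           {self.model.n_obs}",
            f"sigma (regularization): {np.unique(self.sigma)}",
            f"converged:             {self.converged} ({self.n_iter} iterations)",
            f"Gamma at minimum:      {self.gamma_min:.6g}",
            f"Kish effective size:   {self.kish:.1f} / {self.model.n_frames}",
        ]
        if self.chi2 is not None:
            lines.append(f"reduced chi^2:         {self.chi2:.4g}")
        lines.append(f"max |lambda|:          {np.abs(self.lambdas).max():.4g}")
        return "\n".join(lines)


class MaxEntReweight:
    """Maximum-entropy reweighting model.

    Parameters
    ----------
    s_matrix : (n_frames, n_obs) per-frame observable values s_i(x_t).
    s_exp : (n_obs,) experimental targets.
    sigma : scalar or (n_obs,) regularization scale σ_i (> 0). A scalar is
        broadcast — the default mode, applying the same σ to every point of
        the spectrum.
    bias : optional per-frame bias energies V_b(x_t) in kcal/mol.
    kT : thermal energy (kcal/mol), default 300 K.
    se : optional (n_obs,) experimental standard errors used for the
        reduced-χ² diagnostic.
    """

    def __init__(self, s_matrix, s_exp, sigma, bias=None, kT: float = KT_300K,
                 se=None):
        self.s_matrix = np.asarray(s_matrix, dtype=float)
        if self.s_matrix.ndim != 2 or self.s_matrix.shape[0] < 2:
            raise ValueError("s_matrix must be (n_frames >= 2, n_obs)")
        if not np.isfinite(self.s_matrix).all():
            raise ValueError("s_matrix must be finite")
        self.s_exp = np.asarray(s_exp, dtype=float)
        if self.s_exp.shape != (self.s_matrix.shape[1],):
            raise ValueError("s_exp length must equal n_obs")
        self.sigma = np.broadcast_to(
            np.asarray(sigma, dtype=float), (self.s_matrix.shape[1],)).copy()
        if (self.sigma <= 0).any():
            raise ValueError("sigma must be positive")
        self.kT = float(kT)
        if self.kT <= 0:
            raise ValueError("kT must be positive")
        self.bias = None if bias is None else np.asarray(bias, dtype=float)
        if self.bias is not None and self.bias.shape != (self.n_frames,):
            raise ValueError("bias must be per-frame")
        self.se = None if se is None else np.asarray(se, dtype=float)
        # constant log-prior term, max-shifted for stability
        self._logprior = (np.zeros(self.n_frames) if self.bias is None
                          else self.bias / self.kT)

    @property
    def n_frames(self) -> int:
        return self.s_matrix.shape[0]

    @property
    def n_obs(self) -> int:
        return self.s_matrix.shape[1]

    def prior_weights(self) -> np.ndarray:
        return prior_weights(self.bias, self.kT, n_frames=self.n_frames)

    # -- dual function ----------------------------------------------------

    def _log_unnorm(self, lambdas: np.ndarray) -> np.ndarray:
        return self._logprior - self.s_matrix @ lambdas

    def weights_for(self, lambdas: np.ndarray) -> np.ndarray:
        """Posterior weights for a given multiplier vector, normalized."""
        a = self._log_unnorm(np.asarray(lambdas, dtype=float))
        w = np.exp(a - a.max())
        return w / w.sum()

    def gamma(self, lambdas: np.ndarray) -> tuple[float, np.ndarray]:
        """Γ(λ) and its analytic gradient ∂Γ/∂λ_i = s_i^exp − ⟨s_i⟩_w + λ_i σ_i²."""
        lambdas = np.asarray(lambdas, dtype=float)
        if not np.isfinite(lambdas).all():
            raise ValueError("lambdas must be finite")
        a = self._log_unnorm(lambdas)
        value = (logsumexp(a) - np.log(self.n_frames)
                 + lambdas @ self.s_exp
                 + 0.5 * ((lambdas * self.sigma) ** 2).sum())
        w = np.exp(a - a.max())
        w /= w.sum()
        grad = self.s_exp - w @ self.s_matrix + lambdas * self.sigma ** 2
        return float(value), grad

    # -- fitting -----------------------------------------------------------

    def fit(self, init: np.ndarray | None = None, tol: float = 1e-8,
            maxiter: int = 10_000) -> ReweightResults:
        """Minimize Γ by BFGS from the analytic gradient.

        Γ is convex in λ (log-sum-exp plus linear plus positive quadratic),
        so the minimizer is unique. Non-convergence within the iteration
        budget returns the best iterate flagged ``converged=False``.
        """
        x0 = np.zeros(self.n_obs) if init is None else np.asarray(init, float)
        res = scipy.optimize.minimize(
            self.gamma, x0, jac=True, method="BFGS",
            options={"gtol": tol, "maxiter": maxiter})
        lambdas = res.x
        # BFGS may stop on precision loss with the optimum already reached;
        # judge convergence by the gradient itself, on the scale of s_exp
        gscale = max(np.abs(self.s_exp).max(), 1.0)
        converged = (bool(res.success)
                     or np.abs(res.jac).max() <= 1e-6 * gscale)
        weights = self.weights_for(lambdas)
        chi2 = None
        if self.se is not None:
            fit_I = weights @ self.s_matrix
            resid = (fit_I - self.s_exp) / self.se
            chi2 = float((resid ** 2).sum() / (self.n_obs - 1))
        return ReweightResults(
            lambdas=lambdas, weights=weights, kish=kish_size(weights),
            chi2=chi2, gamma_min=float(res.fun), converged=converged,
            sigma=self.sigma.copy(), n_iter=int(res.nit), model=self)

    def tune_sigma(self, grid, target_chi2: float = 1.0,
                   tol: float = 1e-8) -> tuple[float, ReweightResults, list]:
        """Scan a σ grid (same scalar σ for all observables), fitting each.

        Returns the σ whose reduced χ² lands closest to ``target_chi2``,
        its results, and per-candidate diagnostics
        ``[(sigma, chi2, kish), ...]``. Requires ``se`` for the χ².
        """
        grid = np.sort(np.asarray(grid, dtype=float))
        if grid.size == 0:
            raise ValueError("sigma grid is empty")
        if self.se is None:
            raise ValueError("tune_sigma requires experimental errors (se)")
        diagnostics = []
        best = None
        init = None
        for s in grid:
            model = MaxEntReweight(self.s_matrix, self.s_exp, s,
                                   bias=self.bias, kT=self.kT, se=self.se)
            res = model.fit(init=init, tol=tol)
            init = res.lambdas  # warm start the next candidate
            diagnostics.append((float(s), res.chi2, res.kish))
            if best is None or abs(res.chi2 - target_chi2) < abs(best[1].chi2 - target_chi2):
                best = (float(s), res)
        return best[0], best[1], diagnostics


def block_bootstrap(n_frames: int, weights: np.ndarray, statistic,
                    n_blocks: int = 10, n_iter: int = 400,
                    seed: int | np.random.Generator = 0) -> tuple[float, float]:
    """Block bootstrap of a weighted statistic over a frame sequence.

    The frame sequence is cut into ``n_blocks`` contiguous blocks (the last
    may be shorter); each iterate resamples blocks with replacement,
    renormalizes the weights on the resampled frames and recomputes
    ``statistic(frame_indices, weights)``. Returns the mean and standard
    deviation over iterates.
    """
    if n_frames < n_blocks:
        raise ValueError("fewer frames than blocks")
    weights = np.asarray(weights, dtype=float)
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    edges = np.linspace(0, n_frames, n_blocks + 1).astype(int)
    blocks = [np.arange(edges[b], edges[b + 1]) for b in range(n_blocks)]
    vals = np.empty(n_iter)
    for it in range(n_iter):
        chosen = rng.integers(0, n_blocks, size=n_blocks)
        idx = np.concatenate([blocks[b] for b in chosen])
        w = weights[idx]
        w = w / w.sum()
        vals[it] = statistic(idx, w)
    return float(vals.mean()), float(vals.std())
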