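# Methods

This note documents the models, numerical choices and limitations behind
`saxsens`. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Forward model

The scattering of one frame is the exact Debye double sum
`I(q) = Σ_ij f_i f_j sinc(q r_ij)` in double precision with no distance
cutoff; `sinc(0) = 1` covers the self terms and the `q → 0` limit, so
`I(0) = (Σ_i f_i(0))²` holds identically. Atomic form factors use the
standard four-Gaussian-plus-constant coefficients for H, C, N, O, S, P;
an option folds the average hydrogen complement of each heavy atom into
its factor for hydrogen-stripped inputs.

Coarse-grained evaluation maps residues either to one bead at the
heavy-atom center of mass ("single-bead") or to a MARTINI-like table of
1 (ALA/GLY) to 5 (TRP) beads. Bead positions use heavy atoms only,
because deposited structures frequently lack hydrogens. Two bead
scattering tables are available:

- `residue-default`: every bead scatters like an average residue,
  `f(q) = 60·exp(−(q·2.7 Å)²/2)` (≈60 electrons, residue-scale damping).
- `from-structure`: per-kind amplitude = the q = 0 sum of the constituent
  atomic factors, damping length = the bead's internal, f(0)-weighted
  radius of gyration measured on a reference frame.

Both are declared approximations with pluggable tables; they are **not**
the published MARTINI or single-bead scattering parametrizations, which
live in their own prior literature. On a compact atomistic toy the
coarse-grained spectra track the all-atom spectrum within a configured
bound of 25% relative deviation for q ≤ 0.3 Å⁻¹ (asserted in the tests);
accuracy degrades above that range, which is why the package's default
grids stop at 0.3 Å⁻¹.

The solvent-layer term enters the bead factor as
`F = F_vac + contrast · exposure · F_w`, with `F_w` the water-molecule
form factor and `exposure` the per-bead relative solvent accessibility.
Exposure is computed with an in-package Shrake–Rupley routine (Fibonacci
sphere points, probe radius 1.4 Å, normalized so an isolated bead scores
1); users may supply exposures directly. `contrast` defaults to 0 (term
off) and is a user parameter: its published calibration is not
reproduced here.

Experimental curves are 3-column text (q [Å⁻¹], I, σ; `#` comments; the
SASBDB `.dat` dialect parses). Preprocessing follows the study
conventions: an optional centered running average (default window 51
points, shrinking symmetrically at the edges so no padding is invented)
followed by linear resampling onto the analysis grid; extrapolation is
refused. A sparse 19-point grid on (0, 0.30] Å⁻¹ is provided for
steering-style spectrum comparisons; the reweighting stage defaults to a
101-point grid of the same range because measured curves carry hundreds
of points and the refinement consumes the full curve.

## Maximum-entropy reweighting

The dual function Γ(λ) (log-sum-exp of `−λ·s + V_b/k_BT`, plus `λ·s_exp`,
plus the quadratic error term `½Σλ²σ²`) is convex, so the minimizer is
unique. It is minimized by BFGS with the analytic gradient
`s_exp − ⟨s⟩_w + λσ²`, gradient tolerance 1e-8, iteration cap 10⁴;
log-sum-exp and the weight exponentials are max-shifted, so adding a
constant to the bias never changes anything and overflow cannot occur.
Convergence is judged on the final gradient norm (BFGS may stop on
"precision loss" with the optimum already reached); a genuinely
unconverged fit is returned flagged, with the best iterate. At the
optimum `⟨s_i⟩_w − s_i^exp = λ_i σ_i²` exactly — the regularization slack
— which the tests assert numerically.

σ is a single global scalar applied to all observables (per-point σ is
supported but non-default). It is tuned over a log-spaced grid (default
1e-3…10, nine candidates, warm-starting each fit from the previous λ),
selecting the candidate whose reduced χ² against the experimental errors
is closest to 1, the conventional no-overfitting point.

**Intensity scale.** The observables are intensities in arbitrary units,
and since every frame shares the same composition, the overall scale
cannot be absorbed by reweighting — maxent on unscaled intensities is
ill-posed. The pipeline therefore fits a weighted-least-squares scale
factor and drives it to *self-consistency*: the scale whose σ-small
posterior reproduces it when refitted. This fixed point is found by
Steffensen-accelerated iteration (`scipy.optimize.fixed_point`,
xtol 1e-8); σ is then tuned at the converged scale. Tuning σ and the
scale jointly to a common fixed point was tried and rejected: the coupled
iteration can drift into a degenerate overfit solution. Observables enter
the optimizer in relative units (divided by the target intensity) so the
multipliers are O(1) and well conditioned.

Diagnostics: Kish effective sample size `K = (Σw)²/Σw²` (scale-invariant,
1 ≤ K ≤ N) and the reduced χ². The reported final χ² additionally folds
the statistical uncertainty of the reweighted curve — the block-bootstrap
standard error of the weighted mean intensity (10 contiguous blocks, 400
iterates, seeded) — into the denominator in quadrature with the
experimental errors.

## Ensemble characterization

- **Free-energy profiles** over the radius of gyration:
  `F = −k_BT ln p` from the weighted histogram, minimum shifted to zero,
  empty bins undefined (NaN). k_BT defaults to 300 K (0.5962 kcal/mol),
  matching the simulation temperature convention.
- **Compact/extended partition** at an Rg threshold. The threshold is
  stored in Å with an explicit unit field; a printed value of "2.47 Å"
  for a protein-sized complex is physically inconsistent with Rg wells
  near 23 and 29 Å and is interpreted as 2.47 nm = 24.7 Å — the default —
  with a warning logged whenever a threshold falls outside the observed
  Rg range.
- **Weighted PCA** of aligned Cα coordinates (eigendecomposition of the
  weight-averaged covariance; refinement weights by default, unweighted
  by flag since the upstream convention is unstated). The number of
  components is the smallest k reaching the target cumulative variance
  (default 93%).
- **QT clustering** in the k-PC distance space. Each round extracts the
  subset with the largest summed weight whose diameter stays below the
  cutoff; such subsets are cliques of the "distance ≤ cutoff" graph, and
  the round is solved *exactly* with networkx's branch-and-bound
  max-weight-clique search on fixed-point–integerized weights (ties in
  weight fall back to solver order, which is deterministic; frames whose
  weight underflowed to zero still count minimally, so they attach to the
  largest compatible cluster). Clustering runs separately on compact and
  extended frames, so no cluster mixes tags. The representative is the
  medoid. The exact search is practical to a few thousand frames, which
  covers the intended use; the QT and network cutoffs (3 and 5 by
  convention) are expressed in the units of the PC projection space and
  are therefore system-specific configuration — the synthetic benchmark
  uses 35 and 60 to match its own distance scale.
- **Conformational network**: nodes are cluster representatives carrying
  weight and tag; edges join representatives within the distance cutoff;
  node display sizes use a logistic rescaling `w/(w + median)` (midpoint
  at the median cluster weight, one decade growth rate) and are never
  used in statistics.
- **Contacts**: residue pairs are in contact when the minimum heavy-atom
  distance is below 5 Å (closest-heavy); pair probabilities are weighted
  frame fractions, and pairs above 2.5% probability are flagged
  persistent. The implementation is cross-checked against MDTraj's
  closest-heavy contacts in the tests.
- **Cross-links**: tables filtered at spectral score strictly > 30,
  inter-protein by default. Cα–Cα distances are measured after applying
  per-chain numbering offsets (a His-tag offset of 24 is shipped as a
  documented preset, never hard-coded); compliance uses the inclusive
  10–35 Å window of a BS3-style lysine linker. Restraint energies are
  flat-bottom upper walls, `E = ½·k·(d − wall)²` beyond 30 Å with
  k = 23.90 kcal/mol/Å², zero inside, C¹-continuous at the wall.

## Synthetic benchmark

The generator emulates the statistical structure the analysis assumes: a
two-domain protein with one rigid core (beads on a compact lattice,
identical across frames) and one flexible arm grown as a self-avoiding
random walk (bond 3.8 Å, clash distance 3 Å). Compact frames confine the
arm inside a fold shell whose radius varies per frame — giving the
compact state conformational breadth comparable to the extended one —
while extended frames use a persistent outward walk. States are sampled
50/50 in frame counts; populations are carried by weights: the
ground-truth weights place 65% of the mass on extended frames while the
two-level bias concentrates the prior at 1% extended (closed form,
exact), mirroring a compact-dominated enhanced-sampling prior. The target
curve is the true-weighted spectrum on a 101-point grid plus Gaussian
noise of 2% of I(q) — a typical relative error scale for a well-measured
SAXS curve — with that sd reported as the error column. Synthetic
cross-links are core–arm pairs inside the 10–35 Å window in ≥90% of
compact frames and outside it in ≥50% of extended frames, with scores
above the loader's cut. Everything is deterministic under the spec seed.

Default sizes (30 core + 20 arm beads, 300 frames) keep a full benchmark
run around half a minute on one core while leaving the recovery problem
statistically meaningful; the test suite uses smaller instances where a
property does not need the full size.

What passing the benchmark shows — and what it does not: the two-state
toy has a spectral difference between states that is large relative to
noise, a prior that is wrong only in its state populations, and a forward
model identical to the one that generated the target. Real systems add
forward-model error (solvation, coarse-graining), priors wrong in shape
as well as population, and correlated experimental errors; recovery there
will be correspondingly weaker. The benchmark validates the statistical
machinery, not the forward model's physical accuracy.

## Known limitations

- No analytic coordinate gradients of I(q) (on-the-fly biasing is out of
  scope), and no excluded-volume corrections beyond the solvent-layer
  term.
- Bead scattering tables are generic approximations unless the user
  supplies parametrized ones.
- The exact QT round is worst-case exponential; for ensembles far beyond
  ~10³ frames, pre-clustering or subsampling is advised.
- Inputs are assumed whole molecules (no periodic-boundary unwrapping).
- The BFGS dual optimization assumes finite observables; targets far
  outside the convex hull of the frame observables drive Kish toward 1
  and leave χ² high — reported honestly rather than masked.
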