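# saxsens

SAXS-driven maximum-entropy refinement of conformational ensembles.

Flexible, multi-domain proteins and complexes with disordered regions are
poorly described by a single structure: solution experiments such as
small-angle X-ray scattering (SAXS) see a population average over many
conformations. A common integrative strategy is to sample a broad pool of
conformations with enhanced-sampling molecular dynamics (whose bias makes
the frame weights uneven), then *reweight* that prior ensemble so its
average computed SAXS spectrum matches the measured curve — changing the
prior as little as possible — and finally characterize the refined
ensemble: state populations, clusters, a conformational network, contacts,
and agreement with cross-linking mass-spectrometry (XL-MS) distance
restraints. `saxsens` implements that whole workflow for structural
biologists and simulators, together with a synthetic benchmark with known
ground truth so every stage is testable without downloading anything.

## The model

**Forward model.** The rotationally averaged intensity of one structure is
the Debye double sum over particles

    I(q) = Σ_i Σ_j f_i(q) f_j(q) sin(q r_ij) / (q r_ij)

evaluated either over atoms (Cromer–Mann form factors) or over
coarse-grained beads (1 bead per residue, or a MARTINI-like 1–5 beads per
residue), where a bead's scattering factor can include a solvent-layer
term `F(q) = F_vac(q) + c·exposure·F_w(q)` weighted by its solvent
exposure.

**Reweighting.** Given per-frame observables `s_i(x_t)` (the computed
intensities), targets `s_exp`, a bias potential `V_b` from the sampling
and a regularization scale σ, the posterior weights are

    w_t ∝ exp( −Σ_i λ_i s_i(x_t) + V_b(x_t)/k_B T )

with λ minimizing the convex dual

    Γ(λ) = ln⟨exp(−λ·s + V_b/k_B T)⟩ + λ·s_exp + ½ Σ_i λ_i² σ_i² .

The quadratic term models experimental error; σ is tuned so the reduced
χ² between the reweighted and measured spectra is ≈ 1. Diagnostics are
the Kish effective sample size K = (Σw)²/Σw² and the reduced χ². The
refined weights then drive free-energy profiles over the radius of
gyration, compact/extended population splits, weighted PCA +
quality-threshold (QT) clustering, a conformational space network, contact
maps, and flat-bottom cross-link restraint checks.

## Worked example

Generate the synthetic two-state benchmark (a rigid core with a flexible
arm; the prior holds ~99% compact conformations while the true ensemble is
65% extended) and refine it:

```bash
saxsens simulate --outdir bench --seed 1
saxsens run --config bench/config.yaml
```

The run report (also in `bench/results/report.json`) prints, among others:

```
"chi2_fit": 0.938977,
"fraction_compact": 0.35084,
"fraction_extended": 0.64916,
"kish": 264.463,
"n_clusters": 36,
"n_pcs": 5,
"prior_fraction_compact": 0.99,
"prior_fraction_extended": 0.01,
"sigma": 0.1
```

Reading this: the maximum-entropy stage moved the ensemble from a 99%
compact prior to 35% compact / 65% extended — recovering the ground truth
(65% extended) to within a tenth of a percentage point here — while
fitting the target curve within its errors (reduced χ² ≈ 0.94) and
keeping 264 of 300 frames effectively contributing (Kish size). Five
principal components capture ≥ 93% of the coordinate variance and the
weighted QT clustering groups the frames into 36 clusters, none mixing
compact and extended members. `bench/results/` also holds the prior,
reweighted and processed experimental spectra, per-frame weights, the
free-energy profiles over Rg, the cluster table, the network edge list,
contact probabilities and the cross-link compliance table.

The same stages are available as library calls (`saxsens.refine_weights`,
`saxsens.qt_cluster`, ...) and as standalone subcommands
(`spectra`, `reweight`, `analyze`, `xlmap`).

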