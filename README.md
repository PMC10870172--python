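# fretpaths

Photon-level inference of microsecond conformational dynamics from
single-molecule FRET bursts, and correlation-network analysis of coordinate
ensembles — the complete desk-scale toolchain for studying how the
substrate-gripping pore loops of AAA+ disaggregation machines (ClpB-type
hexamers) couple to their ATPase sites.

The package is aimed at single-molecule spectroscopists and simulators who
need, in one place:

* **Burst processing** — inter-photon-gap burst search, ALEX/PIE raw FRET
  efficiency `E` and stoichiometry `S`, leak and direct-excitation correction
  factors estimated from donor-only/acceptor-only contaminants, double-label
  selection, 35-bin FRET histograms.
* **H²MM** — photon-by-photon maximum-likelihood hidden Markov inference for
  a two-state system with fixed state efficiencies. Between photons the state
  propagates by the exact continuous-time transition matrix
  `P(Δt) = Π + (I − Π)e^{−(k₁₂+k₂₁)Δt}`; fitting maximizes the exact
  likelihood over `(k₁₂, k₂₁)` from many random restarts. Includes Viterbi
  decoding, recoloring (posterior-predictive) checks, segmentation and
  dwell-time validation.
* **Kinetics & thermodynamics** — the effective equilibrium coefficient
  `K = k₂₁/k₁₂ = P₁/P₂`, free energies `ΔG = −RT ln K` (T = 295.15 K),
  double-mutant-cycle coupling energies with propagated errors, hexamer
  labeling statistics, and binding-isotherm fits
  `R(c) = 1 + A·c/(K_d + c)` of state-population ratios against substrate
  concentration.
* **Ensemble allostery** — superposition, essential-dynamics PCA with mode
  overlaps / cumulative overlaps / RMSIP, residue cross-correlation networks
  with edge length `−ln|C_ij|`, optimal and up-to-k suboptimal shortest
  paths (Dijkstra/Yen), and overlap coefficients between path-length
  distributions.
* **Synthetic generators** — photon datasets (two-state Gillespie paths,
  leak/direct/background perturbations, contaminant species, PIE
  stoichiometry channel) and Gaussian coordinate ensembles with planted
  covariance, both with ground truth, so the whole chain is testable without
  any experimental download.

See `docs/methods.md` for the models, assumptions and numerical choices.

## Worked example

Simulate a fast-switching two-state system at the measured pore-loop rates,
recover the rates from the photons alone, and compute the equilibrium
coefficient:

```python
from fretpaths import bursts as bp, h2mm, kinetics, simulate

model = simulate.GeneratorModel(k12=44_400.0, k21=20_600.0)   # s^-1
dataset = simulate.simulate_dataset(model, n_bursts=2000, seed=1)

found = bp.find_bursts(dataset.stream(), max_gap=5e-6)
cf = bp.estimate_corrections(found)                   # leak, direct excitation
metrics = bp.compute_metrics(found, cf)
selected, _ = bp.select_double_labeled(found, metrics)

e1, e2 = simulate.apparent_efficiencies(model)        # fixed state efficiencies
fit = h2mm.fit_h2mm(selected, E1=e1, E2=e2, n_restarts=10, seed=2)
K = kinetics.equilibrium_coefficient(fit.model.k12, fit.model.k21)
print(f"k12={fit.model.k12:.0f} k21={fit.model.k21:.0f} K={K:.3f}")
```

Output:

```
k12=44949 k21=21244 K=0.473
```

i.e. the state 1 → 2 and 2 → 1 rates are recovered within ~1–3% of their
generating values from ~1500 selected bursts, and the population ratio of the
low-FRET (up) to high-FRET (down) conformation is `K ≈ 0.46` — the molecule
spends twice as long in the high-FRET state. The same chain run on the
substrate-bound rates (17,700/14,700 s⁻¹) gives `K ≈ 0.83`: substrate binding
shifts the pore loop toward the up conformation.

Thermodynamic coupling between two ATPase-site mutations, from four measured
equilibrium coefficients:

```python
res = kinetics.double_mutant_cycle(0.46, 0.5, 0.7, 0.6)
print(f"coupling = {res.coupling:+.1f} J/mol")   # coupling = +582.9 J/mol
```

A nonzero coupling means the free-energy cost of the second mutation depends
on whether the first is present — the two sites communicate.

There is also a CLI (`fretpaths simulate-photons | bursts | fit | kinetics |
titrate | dmc | simulate-ensemble | pca | paths | run`) mirroring these
stages; `fretpaths run --config cfg.yaml` executes the whole pipeline
reproducibly and stamps every output with the configuration hash.

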