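# Methods

This note documents the models implemented in `fretpaths`, the assumptions
behind them, the synthetic-data generators the tests rest on, and the
numerical choices made where the design was genuinely open.

## The two-state photon-level HMM

A single dual-labeled molecule diffusing through a confocal volume emits a
burst of photons whose colors (donor/acceptor) report its FRET efficiency at
the instant each photon is detected. When the molecule interconverts between
two conformations on the microsecond timescale — faster than a burst, slower
than the inter-photon spacing — the per-burst mean FRET efficiency blurs the
two states together, and inference must operate photon by photon.

The model is a continuous-time two-state Markov chain with rates `k12`
(state 1 → 2) and `k21` (state 2 → 1). State 1 is the low-FRET state with
efficiency `E1`, state 2 the high-FRET state with `E2`; both efficiencies are
held fixed during fitting (they are determined once, upstream, by a global
analysis — here, analytically from the generator, see below). The observation
sequence of a burst is its donor-excitation photons: arrival times
`t_1 < … < t_n` and colors `c_i ∈ {donor, acceptor}`. Between photons the
hidden state propagates by the exact two-state transition matrix for the
elapsed interval Δt,

    P(Δt) = Π + (I − Π) e^{−kΔt},   k = k12 + k21,

where Π has rows equal to the stationary distribution
(π₁, π₂) = (k21/k, k12/k). Because the matrix exponential is closed-form at
N = 2, no clock-tick discretization is needed and the likelihood is exact in
continuous time. Emission probabilities are `b_i(acceptor) = E_i`,
`b_i(donor) = 1 − E_i`. The initial state distribution defaults to the
stationary one (bursts sample molecules at equilibrium); a free uniform `Π`
is available behind a flag.

The per-burst likelihood is computed by the scaled forward recursion; the
total log-likelihood is the sum over selected bursts. Fitting maximizes this
exact likelihood over `(ln k12, ln k21)` by Nelder–Mead simplex search from
many random restarts (default 50, log-uniform initial rates on
[10², 10⁶] s⁻¹). The accepted-likelihood trace within each restart is monotone
non-decreasing; the best restart is returned. Convergence is declared at a
relative log-likelihood change below 1e−9 (cap 3000 iterations, flagged if
hit). The acceptance surface is the likelihood value itself, so any maximizer
of the same objective is equivalent; the simplex search was chosen because the
2-parameter landscape is smooth and unimodal in practice and needs no
expected-statistics approximation.

Derived quantities: populations `P1 = k21/k`, `P2 = k12/k`; the effective
equilibrium coefficient `K = k21/k12 = P1/P2`, the population ratio of the
low-FRET to the high-FRET conformation.

### Validation analyses

* **Viterbi decoding** — log-space dynamic programming with the same
  interval-dependent transition matrices; ties break toward state 1.
* **Recoloring** — a posterior-predictive check: arrival times are kept,
  state paths re-sampled from the fitted model, colors redrawn from the
  emission probabilities, and the 35-bin per-burst FRET histogram recomputed.
  The discrepancy statistic is the sum of squared bin-mass differences
  between data and the replica mean; the data histogram should fall within
  the replica-replica envelope (95th percentile of leave-one-out
  discrepancies).
* **Segmentation** — bursts split at Viterbi transitions; segments with ≥ 5
  photons yield per-segment E values whose histogram should be bimodal at
  the fixed efficiencies.
* **Dwell times** — a dwell runs from the first photon of a state run to the
  first photon of the next run; the first and last run of each burst are
  censored by the burst edges and excluded. Exit rates are reciprocal mean
  complete dwells (the exponential MLE).

**Resolution limits of dwell analysis.** Viterbi dwell estimates are only
meaningful when the photon spacing is much shorter than a dwell and a dwell
much shorter than a burst, with well-separated state efficiencies. Outside
that window the estimator is biased: dwells spanning ≲ 20 photons are merged
across missed short excursions (exit rates biased low — a factor ≈ 2 at
44,400/20,600 s⁻¹ and 500 kHz detection), while dwells comparable to the
burst length suffer window truncation (rates biased high). The dwell-agreement
test therefore runs at 10,000/4,640 s⁻¹ (the same population ratio as the
fast condition), 500 kHz, 2 ms bursts and E = 0.1/0.9, where dwell-MLE and
HMM rates agree to better than 10%. This limitation is intrinsic to
Viterbi-based dwell counting, not to the likelihood fit, which remains
unbiased in the fast regime.

## Burst processing

Burst search uses the literal inter-photon-gap rule: a gap ≥ 5 μs (default)
terminates a burst; runs shorter than 2 photons are discarded. Raw metrics
per burst from the three ALEX counts:

    E_raw = F_DexA / (F_DexD + F_DexA)
    S_raw = (F_DexD + F_DexA) / (F_DexD + F_DexA + F_AexA)

Leak `l` is estimated as the mean raw E of donor-only bursts
(S_raw ≥ 0.8 by default); direct excitation `d` as the mean
`F_DexA / F_AexA` over acceptor-only bursts (S_raw ≤ 0.2). Corrected
acceptor signal: `F_A = F_DexA − l·F_DexD − d·F_AexA`, from which corrected
E and S follow. Values marginally outside [0, 1] are retained for statistics
and clipped only for histogram display, to avoid edge bias. Selection keeps
bursts with corrected S in [0.3, 0.7] (the double-labeled population under a
1:1 excitation duty) and ≥ 30 photons. FRET histograms use 35 uniform bins
on [0, 1], mass-normalized.

The numeric stoichiometry window and the contaminant gates are configurable;
the defaults are standard ALEX practice rather than uniquely determined
values.

## The synthetic photon generator

The generator produces the statistical structure the downstream analyses
assume, with ground truth attached, so every stage is testable without
experimental data. Defaults are one fixed study condition: rates
44,400/20,600 s⁻¹ (equilibrium coefficient 0.46), detection 300 kHz during a
burst, fixed 1 ms bursts, leak 0.05, direct excitation 0.02, 1 kHz background
per channel, 15% donor-only and 10% acceptor-only contaminants, a 1:1
acceptor-excitation duty (`aex_fraction = 1`), 1 ns clock. The state
efficiencies default to E1 = 0.4, E2 = 0.8 — free parameters of the synthetic
study, chosen as a representative mid/high-FRET pair; they are not measured
values.

Per burst: the latent path is a Gillespie draw (exponential holding times,
stationary initial state). Photons form a renewal stream whose gap law is a
truncated exponential supported below 4.5 μs, with the rate solved
(Brent root-finding) so the mean gap equals the reciprocal total detection
rate. This guarantees every simulated burst is recoverable by the 5 μs gap
rule — with plain exponential gaps at 300 kHz, about one gap in five would
exceed the cutoff and fragment every burst. Because the HMM conditions on
arrival times, the gap law does not perturb the color statistics it infers
from; only the (uninformative) interval distribution differs from a Poisson
process. Each photon is then typed multinomially by rate fraction (state
emission, direct excitation, background D/A, acceptor-excitation), emission
photons are colored acceptor with probability `E_state`, donor photons flip
to the acceptor channel with probability `leak`, and timestamps are quantized
to clock ticks with ties resolved by +1 tick. Donor-only bursts emit at
E = 0 (plus leak); acceptor-only bursts carry only acceptor-excitation,
direct-excitation and background photons. Bursts are separated by 100 μs
gaps (20× the search cutoff), so burst recovery is unambiguous and exact.

Because leak, direct excitation and background mix state-independent photons
into the donor-excitation stream, the efficiencies the HMM observes are not
the emission values; `apparent_efficiencies` returns the closed form

    E_app,i = (ρ(E_i + (1−E_i) l) + δ + β_a) / (ρ(1+direct) + β_d + β_a)

(ρ the emission rate, δ the direct rate, β the backgrounds). Fits of
generator data fix E1/E2 at these apparent values — the synthetic analogue of
taking the fixed efficiencies from a prior global analysis. With
state-independent photon rates the merged stream remains an exact two-state
HMM with these emission probabilities, so rate recovery is unbiased; an
optional per-state brightness multiplier breaks this exactness and is off by
default.

What the generator does **not** emulate: diffusion through a 3-D Gaussian
excitation volume (burst intensity envelopes, burst-size distributions),
triplet blinking and photobleaching, and TCSPC nanotimes. Passing tests
therefore demonstrate correctness of the estimators under the stated
generative model, not robustness to those photophysical effects.

## Kinetics and thermodynamics

* `K = k21/k12 = P1/P2`; consistency between rates and populations is
  asserted to 1e−9.
* Labeling statistics: a 1:r labeled:unlabeled protomer mix gives
  Binomial(6, p) labeled protomers per hexamer with `p = 1/(1+r)` (the exact
  mixture fraction; at r = 100 the single-labeled probability is 5.7%).
* Free energies: `ΔG = −RT ln K`, R = 8.314 J mol⁻¹ K⁻¹, T = 295.15 K
  (configurable).
* Double-mutant cycles over (wt, B1, B2, BB): edges
  `ΔΔG(X→Y) = ΔG_X − ΔG_Y`; coupling = difference of opposite edges,
  identically `−RT ln[(K_wt K_BB)/(K_B1 K_B2)]`. Errors propagate first-order
  (δΔG = RT·se_K/K) and in quadrature along edges.
* Binding isotherms: the state-1 population ratio against ligand
  concentration is fit to `R(c) = 1 + A·cʰ/(K_dʰ + cʰ)` with A ≥ 0, K_d > 0,
  Hill exponent h = 1 by default. The single-site hyperbola anchored at
  R(0) = 1 is the minimal model for a saturating ratio curve; flat data pin
  A at 0 and flag K_d as unidentifiable.

## Ensemble analysis

Superposition least-squares fits every frame onto the ensemble mean over the
selected atoms (Kabsch SVD with reflection guard), recomputing the mean once
and fitting again. PCA diagonalizes the covariance of the flattened selected
coordinates; eigenvalues are reported in Å² with variance fractions, and a
warning is issued when frames do not exceed coordinate dimensions. Subspace
similarity: mode overlap `|u·v|`, cumulative overlap `√Σ_j (u·v_j)²` against
an orthonormal basis, and RMSIP over the top-10 modes — all invariant to
orthonormal re-basis of either subspace.

Residue cross-correlations are normalized covariances of Cα displacement
vectors. The allosteric network places nodes at Cα positions and connects
residue pairs within 8 Å in ≥ 75% of frames (a standard dynamical-network
contact criterion — some locality constraint is required, or the −ln|C|
weighting connects everything); edge length is `−ln|C_ij|` with |C| clamped
to [1e−6, 1−1e−6] to keep weights finite and positive, so stronger coupling
gives shorter edges. Shortest paths come from Dijkstra (optimal) and Yen's
algorithm (up to k = 200 suboptimal simple paths), with equal-length ties
ordered lexicographically for determinism. Path-length distributions are
compared by the overlap coefficient on a common 30-bin grid spanning the
pooled range (histograms rather than kernel densities: reproducible and
parameter-light); per-protomer OCs are averaged with SD.

The planted-network generator produces a correlation matrix whose backbone
chain is, by construction, the unique −ln|C| shortest path between its
endpoints; it raises a degeneracy error when the off-backbone correlation
admits a shortcut at least as short (`off ≥ backbone^(L−1)`).

## Pipeline, formats, reproducibility

All randomness derives from one integer seed through `numpy.random`
SeedSequence spawning; the same seed reproduces a dataset byte-for-byte.
Photon data travel as TSV (one photon per row) or an HDF5 container with one
group per burst (`timestamps`, `detectors`), with a ground-truth sidecar TSV.
Ensembles load from multi-model PDB (via biotite) or a plain XYZ-per-frame
table. Every pipeline output carries the SHA-256 hash of the resolved
configuration; unknown configuration keys are rejected.

Problem sizes used by the shipped checks — 7,000-burst datasets (≈ 2 million
photons) for rate recovery, 1,200–2,500 bursts for dwell and recoloring
checks, 50,000-frame ensembles for PCA mode recovery, 500 random graphs for
the path oracle — were chosen so each estimate's sampling error sits well
inside the tolerance it is compared against.

## Known limitations

* Only the fixed-efficiency two-state model is implemented; no N-state
  fitting or model selection.
* Dwell-time analysis is biased outside its resolution window (see above).
* The isotherm parameterization and the network contact criterion are
  documented package choices, not uniquely determined by the measurement
  they model.
* The generator's burst-duration law (fixed or exponential) ignores
  diffusion-limited burst-size statistics; selection thresholds interact
  with that simplification.
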