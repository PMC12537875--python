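# Methods

This note documents the models, estimators, numerical choices, and known
limitations of helixevo, in the order a user meets them.

## Palindromic sequence encoding

A length-L peptide (L even, default 20) is encoded by its first L/2
residues; the phenotype is `free + reversed(free)` and reads identically in
both directions. The encoding assumes a symmetric bilayer, in which the two
membrane leaflets — and hence the two halves of a transmembrane helix — are
physically equivalent. It reduces the search space from 20^L to 20^(L/2)
and guarantees that crossover and mutation, which act on the free
half-genome only, always produce valid mirror-symmetric candidates.
Asymmetric membranes would need a non-palindromic genome; this is out of
scope.

Positions are 0-based internally; every reported position (motif anchors,
TSV output) is 1-based, following bioinformatics convention.

## Template grammar and the block-scan family

Peptide templates are strings of blocks `<residue-or-group><count>`, with
bracketed groups repeating as a unit (`"GK2[LA]7LK2A"` → GKK(LA)₇LKKA,
21 residues, contiguous L/A core of 15). The hydrophobic block-length scan
family is D₂KₖLₓKₖD₂ with k = 8 − x/2 so that every member is exactly 20
residues: the printed flank subscript in the family's usual notation is
arithmetically inconsistent with a 20-residue total, and the explicit
20-residue examples take precedence. x must be even (palindromy) and ≤ 16
(non-negative flanks).

## Genetic algorithm

Defaults follow the converged production setting: population 128, parent
pool 16, 2 iteration elites + 2 rerun elites, mutation rate 1/20 per free
residue, 40 generations.

Decisions where the procedure was genuinely open:

- *Rerun averaging.* A reoccurring sequence is re-evaluated and its
  recorded fitness is the equal-weight running mean of all evaluations.
- *Parent sampling.* Two parents per child, uniform with replacement from
  the pool, distinct when the pool has ≥ 2 members.
- *Crossover point.* Uniform on 1..L/2−1, so both parents always
  contribute.
- *Mutation.* Replacement is uniform over all 20 symbols, self-replacement
  allowed; the effective change probability per position is 19/400.
- *Ranking ties.* Broken by (fitness desc, number of evaluations desc,
  lexicographic sequence) so runs are fully deterministic under a seed.
- *Elite overlap.* Iteration and rerun elites are deduplicated; the
  remainder of the population is filled by recombination.
- *Backend failures.* A failing fitness evaluation records −inf rather
  than aborting the run, since production runs are long and unattended.

With a deterministic backend and ≥ 1 iteration elite, the best ledger
fitness is non-decreasing across generations (asserted in tests).

## Fitness backends

`fitness_from_energy_series` implements the production definition: the
absolute mean interaction energy over frames at or after the equilibration
cutoff (default 50 ns; times in ps). `read_xvg` accepts two-column
whitespace text with `#`/`@` comment lines.

`surrogate_fitness` is a deliberately simple, non-physical closed form used
for desk-scale runs and as a labeled-data generator. With b the longest
contiguous hydrophobic run (over ACGILMPVFWY) and L = 20:

    score = 10.0 * (# K/R stacked directly against the block, ≤3 per side)
          +  4.0 * (# D/E within the two first/last positions)
          +  3.0 * (L − b)                 if b ≥ 6   (mismatch reward)
          − 25.0 * (6 − b)                 if b < 6   (instability penalty)
          −  8.0 * (# F/Y/W)
          − 0.05 * Σ residue volume (Å³) inside the block

Its optimum expresses the same qualitative pattern the MD-driven
optimization selects — a short small-residue hydrophobic block flanked by
stacked lysines/arginines with acidic termini, and a penalty on aromatics —
and, being a documented closed form, admits an exhaustive-search oracle
(verified over the full 4^10 palindromic space of a 4-letter alphabet).
Passing tests against the surrogate demonstrate correctness of the GA
machinery, not membrane physics.

`emit_run_recipe` records the coarse-grained production protocol (500 ns
NPT, 30 fs step, 300 K velocity-rescale thermostat with 3 groups,
semi-isotropic Berendsen barostat, softcore insertion λ = 0.75, 90 POPC +
38 CHOL + 1598 water beads, optional flat-bottom restraints at 1000
kJ mol⁻¹ nm⁻², NC3 2.0 nm / ROH 1.5 nm) as a key = value file plus a JSON
manifest with charge bookkeeping (K/R = +1, D/E = −1, histidine neutral
given its ambiguous pKa; counter-ions = |net charge|). Nothing is executed.

## Cholesterol-ratio statistic

"Within a cylinder" is implemented as a lateral (xy) minimum-image distance
cutoff with no z bound — a bilayer-spanning cylinder. Radii must not exceed
half the smallest lateral box length (minimum-image ambiguity). The
reference point per lipid is a single supplied coordinate; the caller
decides COM vs head bead. `ratio_at` interpolates the cumulative counts
linearly and reports NaN (missing, not zero) where both counts vanish. The
default report radius is 1.0 nm, a middle ground between locality and
sampling. The 90 POPC + 38 CHOL template composition gives the 30% baseline
(38/128 = 0.297).

## WHAM

Binned-histogram WHAM with bin width equal to the grid spacing (default
0.02 nm): iterate window free-energy constants f_i until max |Δf| < 1e-7
kJ/mol (max 1e5 iterations), then G = −kBT ln(unbiased density),
min-normalized to 0. Empty bins outside the sampled span are dropped;
an interior gap (non-overlapping windows) is an error naming the gap.
The output is gauge-invariant under constant shifts of the bias energies.
Statistical uncertainty, when needed, should use a moving-block bootstrap
with block length of order the autocorrelation time; a bootstrap helper is
intentionally not bundled because the PMF tests compare against exact
synthetic references instead.

## Autocorrelation, diffusion, residence time

θ is the one-sided integrated autocorrelation time, θ = dt·Σ_{k≥0} ρ_k,
summed to the first lag where the ACF estimate drops below zero. This is
the convention under which D = Var(x)/θ is exact for an
Ornstein–Uhlenbeck process (θ → the relaxation time 1/(βDk)), making the
estimate invariant to the bias spring constant — verified across
k ∈ {50, 250, 1000} kJ mol⁻¹ nm⁻². Note the two-sided MCMC convention
(1 + 2Σρ) would double θ and halve D. White noise gives θ ≈ dt.

D(x) is interpolated linearly between window centers and held constant
beyond the outermost ones. The residence-time double integral is evaluated
by nested composite trapezoids on the profile grid densified 4-fold; on a
flat landscape with constant D it reproduces the closed form
((b−x0)² − (a−x0)²)/(2D) to 4 digits. Temperature defaults: 303.15 K for
profile work (the atomistic protocol), 300 K for coarse-grained unit
conversions; always explicit in `ThermalContext` (kB = 0.0083145
kJ mol⁻¹ K⁻¹). `arrhenius_ratio` assumes an unchanged kinetic prefactor:
exp(ΔΔG/kBT); 14 kBT ↦ 1.2 × 10⁶.

## Motif scanning and logos

Spacer X means any residue, including members of the anchor classes; all
anchor triples are reported, not just the leftmost, since presence
statistics need any-match semantics and density statistics need all
matches. Both CRAC and CARC are read N→C; CARC is the inverse-order
pattern, not a reversed scan. The CCM (cholesterol consensus motif) is not
implemented: its published definition ("switch Y/F and L/V within the CRAC
algorithm") is too under-specified to encode responsibly.

Logo information is R_i = log₂20 − H_i with 0·log 0 = 0; letter heights are
p_i(a)·R_i. No small-sample correction by default (GA sequence sets are
large); the standard (s−1)/(2 ln2 · n) correction is available via a flag.
`mirror_check` reports per position-pair total-variation distances and is
identically zero on palindromic sets.

## TMD window normalization

Spans longer than 20 residues are rejected (`too_long`); spans of 20 pass
unchanged; shorter spans are extended as evenly as possible with adjacent
protein residues. Open details decided here: an odd deficit puts the extra
residue on the N-terminal side (configurable); when a flank hits a protein
terminus the remaining deficit shifts to the other side, and a window is
rejected (`terminus`) only when the whole protein is shorter than 20 —
chosen to maximize retained data, with the extensions logged per window.
Quality-flag filtering is a pass-through predicate (≥ 10 flags) because
flag semantics live in the source database. accepted + rejected = input
spans always.

## CNN fitness surrogate

One-hot 20×20 input; conv(128 filters, kernel 3, valid) → ReLU → max-pool 2
→ conv(128, kernel 3) → ReLU → max-pool 2 → flatten → dropout p = 0.005 →
dense 36 → ReLU → dense 36 → ReLU → linear output. MSE loss, Adam
(lr 0.001, β = 0.9/0.999), 16 epochs, batch 64. Data: 20% seeded holdout,
remaining 80% in 4 disjoint folds for cross-validation. Kernel size,
pooling width, activation, optimizer, and loss were open choices; the
values above are conventional 1-D sequence-regression defaults. Dropout
0.5% is taken literally as p = 0.005. Labels are z-scored during training
and un-scaled at prediction, a purely numerical conditioning choice.

The network and its gradients are implemented directly in numpy (im2col
convolutions, argmax-routed pooling, inverted dropout); training is
deterministic under a fixed seed in single-threaded execution (BLAS
threading can perturb the last bits; determinism is asserted on same-seed
pairs within a process). On 20,000 synthetic surrogate-labeled random
sequences (16,000 train / 4,000 holdout) the holdout R² is ≈ 0.84 — a
scaled-down analogue of a full-data benchmark; it measures the network's
ability to learn the surrogate's closed form, not MD fitness.

## Synthetic-data generators

- *PMFs*: sums of Gaussians with analytic gradients, so WHAM and the
  kinetics have exact references. The built-in double well spans
  0.7–2.3 nm with ~2 kBT features; the single well is 2 kBT deep at
  0.9 nm by default.
- *Langevin*: Euler–Maruyama, x ← x − βD G′(x) dt + √(2D dt) ξ, optional
  harmonic bias and reflecting boundary by position mirroring. A stability
  check requires βD·k_max·dt < 1 (k_max = stiffest local curvature probed
  on a grid). Defaults D = 0.05 nm²/ps, dt = 0.01 ps keep the per-step
  relaxation ≤ 0.25 for bias k ≤ 250, bounding the discretization bias of
  stationary variances to a few percent. Umbrella series use 60,000 steps
  per window after a 2,000-step burn-in — enough that WHAM's statistical
  error stays well below the 0.2 kBT comparison level.
- *MFPT*: all walkers stepped together as one vector; started at a,
  reflected at x0, absorbed at b; 2,000 trajectories by default.
- *Snapshots*: peptide at the lateral box center; lipid reference points
  drawn from piecewise-constant areal densities over annuli with uniform
  angles, wrapped periodically. Defaults mirror the template membrane
  (90 POPC + 38 CHOL in a 5.6 × 5.6 × 10 nm box).
- *Landscapes*: separable per-position weight tables with the analytic
  argmax optimum returned alongside (GA convergence oracle), plus a rugged
  variant with random pairwise epistasis for population-size comparisons.
- *Proteomes*: random proteins with non-overlapping TM spans of controlled
  lengths for window-normalization bookkeeping.

What the generators do **not** emulate: real lipid geometry or dynamics
(snapshots are independent draws, not trajectories), correlated
multi-dimensional reaction coordinates, sequence composition of real
proteomes, and any force-field physics. Tests passing on this synthetic
data certify the estimators and algorithms, not biological conclusions.

## Problem sizes

Default desk-scale sizes used by the test suite and the reproduction
script: 9 umbrella windows × 60,000 samples; 2,000 first-passage
trajectories; 3 × 100,000-step biased runs for diffusion; GA 128 × 40
generations × 3 seeds; 1,000 random 30-mers for motif enumeration; 10
random 200-point snapshots for the count oracle; 20,000 labeled sequences
for the CNN. These were chosen so each estimator's statistical error sits
comfortably below its comparison level while the whole suite runs in a few
minutes on one CPU.

## Known limitations

- The surrogate fitness is a caricature; only its documented qualitative
  structure is meaningful.
- WHAM assumes uniform bins and histogram (not MBAR-style binless)
  estimation; very sparse tails are dropped rather than extrapolated.
- The integrated-ACF cutoff (first negative lag) is simple and
  bias-bounded but noisy for very long-correlated series.
- The CNN is a small fixed architecture with no search; its benchmark is
  against synthetic labels.
- Window normalization parity/terminus rules are one reasonable reading of
  an under-specified procedure; both are configurable or logged.
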