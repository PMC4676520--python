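# Methods

## The model

A transcription factor (TF) and its DNA binding site (TFBS) are a pair of
sequences of common length `ell` over {A, C, G, T}.  The protein sequence
records amino-acid *preference categories* (each interface amino acid is
labelled by the base it prefers to hydrogen-bond), so both loci live in the
same quaternary space and are mutated identically; the alphabet size is fixed
at 4 and is deliberately not a parameter.

**Binding.**  Under the two-state (match/mismatch) approximation every
mismatched position adds `delta_eps` (default 3 kBT) to the specific binding
free energy, measured from the perfect binder:

    dG(r) = delta_eps * r,    r = Hamming distance between the two loci.

Specific binding competes with a sequence-independent electrostatic mode of
free energy `ell * delta_eps_ns` (default `delta_eps_ns` = 1.5 kBT per site,
calibrated so that the best specific binder of an `ell = 10` site beats the
nonspecific mode by 15 kBT, as for the Lac repressor).  Specific recognition
survives only while `dG(r) <= ell * delta_eps_ns`, i.e. while

    r <= r* = floor(ell * delta_eps_ns / delta_eps).

With the default energies `r* = ell/2` (rounded down).  For odd products the
floor is the conservative reading of "beyond this point the site is
nonfunctional"; `BindingModel(r_star_override=...)` exposes the threshold for
sensitivity analyses (e.g. `ell = 5`, where empirical restriction-enzyme data
suggest a threshold nearer 3 than the floor value 2).

**Fitness.**  Malthusian fitness is a truncated quadratic in the mismatch
number:

    F(r) = -kappa_F r^2 / 2    (r <= r*),        F = INVIABLE  (r > r*).

`kappa_F` (per mismatch², Malthusian units) sets the curvature of stabilizing
selection.  The inviable branch is a typed sentinel, never a floating
`-inf`, so lethal mutants contribute exact zeros to rate sums.

**Evolution.**  In the weak-mutation regime (`n mu0 Ne << 1`) the population
is monomorphic and evolves by origin-fixation: each of the `6 ell` one-step
mutants fixes at rate `k(dF)/3`, with the diploid Kimura rate

    k(dF) = 2 mu0 Ne (1 - e^(-2 dF)) / (1 - e^(-4 Ne dF)),

`dF` the fitness change and `mu0` the per-position mutation rate.  The
dynamics depend on selection essentially through the scaled population size
`4 Ne kappa_F`; parameters may be given as `(Ne, kappa_F)` or as the scaled
product (in which case `Ne` defaults to 1000 and `kappa_F` is back-solved).
Internally time is `mu0 * t` (`mu0 = 1`); the CLI can convert to generations
given a user `mu0`.

**Stationary theory.**  The number of sequence pairs in mismatch class r is
the exact integer

    Omega(r) = 4^ell * C(ell, r) * 3^r,

with sequence entropy `S(r) = ln Omega(r)` and free fitness
`Phi(r) = F(r) + S(r) / (4 Ne)`.  The stationary law over classes is

    p(r) ∝ exp(4 Ne Phi(r)) = Omega(r) exp(4 Ne F(r)),   r <= r*,

computed in log space (log-gamma entropy), so large `ell` or `4 Ne kappa_F`
never overflow.  The analytic mean per-site substitution rate is

    <k> = (2 Ne mu0 / 3 ell) * sum_r p(r) [ r (pi_-(r) + 1/Ne)
                                            + 3 (ell - r) pi_+(r) ],

with `pi_±` the fixation probabilities of the class-changing moves and
`pi_+(r*) = 0` at the cliff; the `r/Ne` term carries the `4r` within-class
neutral mutants.  Neutral checks: without the cliff `<k> = mu0` exactly;
with the cliff `<k> = mu0 (1 - p(r*) (ell - r*)/ell)`, which for `ell = 10`
is `1 - 0.5 * 61236/81922 ≈ 0.626 mu0`.

**A note on exact detailed balance.**  With the full Kimura form the rate
ratio of a move and its reverse is `exp((4 Ne - 2) dF)`, so the chain's
*exact* stationary exponent is `4 Ne - 2`; the diffusion-scaled form
`k = mu0 x / (1 - e^(-x))`, `x = 4 Ne dF`, balances at exactly `4 Ne`.  The
two laws differ at O(dF), far below Monte Carlo resolution in every regime
studied.  The simulator uses the full form by default (`rate_form="full"`);
analytic functions default to the `4 Ne` convention, and
`equilibrium_distribution(..., exponent_shift=-2)` selects the law that is
exactly stationary under full-form rates (the `ell <= 3` brute-force chains
confirm both pairings to 1e-15 total variation).  Detailed-balance residuals
are therefore checked with each rate form against its own exact law.

## Simulation engines

*Object-level* (`tfdmi.engine`): one lineage, one `SubstitutionEvent` per
step; waiting times `-ln(u)/K` with `K` the summed mutant rates (exponential,
so substitution epochs are Poisson).  The full `6 ell` rate table is
recomputed each step; because rates depend on the sequence pair only through
per-position match status, the table takes at most three distinct values, and
the O(1) class summary (`class_rate_summary`) is proven equal to the
aggregated table on a thousand random states in the test suite.

*Vectorized bulk* (`tfdmi.divergence.simulate_pairs`): up to millions of
replicate pairs advance together as a numpy sweep; each round draws the next
event (or censoring) of every active pair, picks the lineage, mutant class,
position and letter in proportion to the same class rates, updates mismatch
and hybrid counters incrementally, and absorbs pairs whose hybrids cross the
cliff.  The two engines are equivalent in law — both are sequence-level and
use the same rate tables — and both are validated against the `ell = 2`
joint-chain matrix-exponential oracle.

**Divergence experiment.**  The common ancestor is drawn with `r0` from the
stationary law and a uniform sequence pair within the class (the stationary
law is uniform within classes), then duplicated.  Hybrid distances
`h12 = dH(p1, d2)`, `h21 = dH(p2, d1)` change only at substitutions and by at
most 1.  A DMI is the *first passage* of `max(h12, h21)` above `r*`
(absorbing); an instantaneous-presence (non-absorbing) convention is
available in `run_replicate(mode="instantaneous")` for comparison — the two
coincide at the early times that carry all quantitative results.  `P_I(t)` is
the empirical first-passage CDF with Wilson 95% intervals; censored
replicates count as zero up to their horizon.  Reproductive isolation over a
genome of `M = 1e5` interacting pairs (10 partners x 2e4 genes / 2) is
`P_RI = 1 - (1 - P_I)^M`, and `t*` is the first crossing of `P_I = 1/M`,
located by log-log interpolation between bracketing grid points (50 points
per decade; if the lower bracket has zero events the crossing is reported at
the bracketing grid point rather than extrapolated, a < 5% grid-resolution
effect).  Bootstrap CIs for `t*` resample the grid-binned first-passage
counts multinomially (200 resamples).

## Numerical choices

- Kimura rates: `expm1`-based evaluation with a first-order series branch
  below `|4 Ne dF| = 1e-8` (continuous to ~1e-12) and log-space asymptotics
  beyond `|4 Ne dF| = 700`; inviable targets return exact 0.
- Degeneracies are exact Python integers; entropies use log-gamma.
- Zero-rate mutants are never candidates for selection (no division by zero
  at the cliff); if *every* mutant is lethal (`ell = 1`, `r* = 0`) the lineage
  is censored at the horizon.
- RNG: numpy PCG64; replicate sweeps draw from one generator, scripts derive
  independent child streams from the master seed via `SeedSequence`.  Fixed
  seed implies bit-identical tables.

## What the generator emulates — and does not

The replicate generator *is* the study system: monomorphic lineages on the
mismatch landscape.  It does not emulate polymorphism, clonal interference,
recombination, unequal protein/DNA mutation rates, heterozygote rescue,
position-specific energies, or genomic background binding — all deliberate
simplifications of the underlying biophysics.  Passing tests therefore
validate the model's internal predictions, not quantitative agreement with
any real TF-TFBS pair.

## Scales used in the shipped checks

Analytic quantities are checked exactly.  Stochastic checks use scales chosen
to keep the whole suite desk-scale while leaving tolerances intact: the t*
measurement uses the full 1e6 replicate pairs to `mu0 t = 0.002`
(`4 Ne kappa_F = 0.04`, threshold 1e-5, accepted within a factor of 2); the
early-slope check 1e5 pairs to 0.05; occupancy-vs-theory 16 pairs to
`mu0 t = 500` per scaled size (ancestors start in stationarity, so no burn-in
is needed and TV noise is ~1e-3 against a 0.05 tolerance); the substitution-
rate cross-check 50 lineages to `mu0 t = 500`; length sweeps 2-3e4 pairs at a
reduced RI threshold of 1e-3.  Monte-Carlo-vs-oracle envelopes are exact
binomial bounds, Bonferroni-corrected so the whole curve is covered at 99%.

## Known limitations and observed subtleties

- `<k>` versus `4 Ne kappa_F` is not globally monotone: between the drift
  plateau (~0.63 mu0) and the selection collapse there is a shallow hump
  (~0.70 mu0 near `4 Ne kappa_F = 0.4`), because leaving the half-blocked
  boundary class initially frees up-moves.  Simulations confirm the analytic
  curve.
- Equilibrium-drawn ancestors can show slightly *higher* early `P_I` than
  fixed-mean ancestors: boundary ancestors (`r0 = r*`) are rate-limited
  because their up-moves are blocked, while `r0 = r* - 1` ancestors reach a
  DMI through two unblocked nearly neutral moves.  The two modes agree within
  a factor of ~1.5 everywhere tested, consistent with "nearly identical" on
  the decade scales of interest.
- `min_substitutions_to_DMI` searches one canonical ancestor per mismatch
  class; this is exhaustive up to the position-permutation and alphabet-
  relabelling symmetry of the map (an independent full enumeration at
  `ell = 2` agrees).
- The ancestor-distribution and P_I-curve shapes at very large
  `4 Ne kappa_F` (>> 40) are exponentially slow to sample; analytic results
  remain available there.
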