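# Methods

This note records the models implemented in `dhtpoly`, the assumptions behind
them, the parameters that matter, and the places where a genuine design choice
had to be made.

## Tile grammar and the activation cascade

A DNA hairpin tile (DHT) is a double-crossover motif built from four strands:
a duplex core, strands providing single-stranded sticky ends, a strand whose
3' end is a 6-nt toehold, and a hairpin strand (stem–loop) that keeps the tile
metastable. Sequences are stored 5'→3'; domains are 0-based half-open
intervals; complementarity is always checked as the reverse complement of the
partner's annotated interval.

Validation rules are structural, not thermodynamic: four strands per tile,
declared sticky pairs reverse-complementary, hairpin stem halves
reverse-complementary, and the toehold single-stranded (no other strand of the
tile may contain its complement). Violations are returned as data so a design
tool can report all of them at once.

Hairpin opening is a topological flag replayed by `sdr_cascade`: the closed
loop is what prevents spontaneous polymerization, so a boolean open/closed
state per tile captures the mechanism without a nearest-neighbor free-energy
model. The cascade terminates either by closing a cycle (the exposed segment
re-targets an already-open tile) or by running out of targets; the closed
three-event cycle I→A→B→A, with the closing segment GTGACA identical to the
initiator's 3' active segment, is the signature of a well-formed system.

The crossover-separation rule is encoded exactly as stated for this system:
separation in nt / 10.5 bp per turn, rounded to the nearest half-turn; an
integer number of turns places the next monomer on the opposite side (2D
growth), a half-integer on the same side (1D growth). The underlying helical
phase convention relative to classical DX-array designs is deliberately not
re-derived; the rule is a faithful transcription, flagged as such.

Tile dimensions use 0.34 nm/bp rise, 2.25 nm helix diameter, and a
configurable 0.5 nm inter-helix gap so a 47-bp DX tile reads 2.25 × 5 × 16 nm.

## Living chain-growth simulator

**Repeat-unit propagation.** The propagating unit is one A–B pair: an active
terminus that has just incorporated B exposes the same 6-nt segment the
initiator carries, so every chain is I-[A-B]_k and alternation is exact by
construction. Treating the pair as one event is what makes the fast-mixing
limit exactly solvable. A consequence worth stating: running strict
single-tile alternation with equal A and B pools to exhaustion would force
every chain to an even tile count and make the per-chain A-counts
underdispersed relative to Poisson; the paired-unit mechanism is the one
consistent with Poisson-distributed label counts, which is the defining
signature of living polymerization that this package exists to reproduce.

**Ideal mode.** Because the initiator's invading segment is
sequence-identical to the propagating segment, initiation and propagation
have the same toehold kinetics, and in the fast-mixing limit every repeat
unit lands on a uniformly random initiator site. The simulator draws the
exact multinomial allocation of `ratio_MI × n_initiators` units over
`n_initiators` sites. Sites with zero units remain free initiators (these are
the experimentally invisible molecules that motivate zero-truncated
statistics). Per-site unit counts are Poisson(ratio) up to the negligible
multinomial correction (variance factor 1 − 1/n).

Closed forms used by the tests, with μ = ratio_MI the mean repeat-unit count:

- tile count per site = 2k, k ~ Poisson(μ); untruncated tile-count
  PDI = (1 + μ)/μ (2.0, 1.5, 1.2, 1.1 at ratios 1, 2, 5, 10);
- detected (k ≥ 1) unit counts are zero-truncated Poisson(μ);
- at ratio 1 the detected single-unit fraction is e⁻¹/(1 − e⁻¹) = 58.2%,
  against the measured 62%;
- mean contour length at ratio 10 is 2 × 10 × 16 nm = 320 nm, against the
  AFM 332 ± 45 nm.

**Kinetic mode.** An exact Gillespie simulation over
I + unit → chain (k_init · n_I · n_units) and chain + unit → chain
(k_prop · n_chains · n_units). The default is k_init = k_prop, reflecting the
sequence identity above; with equal rates the kinetic mode reproduces the
ideal mode's moments, which the tests check at 2000 initiators. k_init is a
sensitivity dial (slow initiation gives fewer, longer chains), not a fitted
quantity — no rate constants are reported for this chemistry.

**Thermal mode.** The no-initiator control at 45 °C is modeled as step-growth
condensation at extent of reaction p: tile counts are Flory most-probable
(geometric), PDI → 1 + p. The experiment's conversion is unknown, so p is a
free parameter; p = 0.99 (PDI ≈ 1.99) is the canonical high-conversion
contrast. Chains are drawn until the monomer budget is spent, which conserves
mass to within the final draw.

**Dispersity contrast.** At matched mean length the thermal PDI exceeds the
living PDI among detected filaments at every ratio — this is the observable
comparison, since AFM cannot see zero-length objects and geometric chains
have no zero class. Untruncated, the strict inequality holds for ratios ≥ 2;
at ratio 1 the two-tiles-per-unit granularity puts the untruncated living
tile-count PDI at exactly 2.0, an artifact of counting invisible empty sites
together with quantized pair additions, which is why the tests compare the
truncated (detected) populations there. Note the detected tile-unit PDI at
ratio 1, (1 + μ)(1 − e^(−μ))/μ = 1.264, falls inside the measured 1.21–1.26
range without any noise tuning.

**Re-feeding.** `extend_population` resumes growth on existing chains only,
leaving never-initiated free initiators untouched; chain count is therefore
invariant, and the mean length is exactly linear in the cumulative ratio.
Allowing dormant initiators to fire during re-feeding would be a defensible
alternative; the simpler contract was chosen because the observable — linear
growth of the mean — is identical and the restart semantics stay trivial to
reason about. The initiator's own contour contribution defaults to 0 nm
(configurable) since its strand is short compared to one 16 nm tile.

## Dispersity statistics and Poisson fits

Ln, Lw, σ and PDI = Lw/Ln are computed directly from the definitions; σ uses
the population 1/N form deliberately (matching how the microscopy statistics
were computed), not 1/(N−1). Statistics are always computed on raw values;
histogram binning (default width 16 nm = one tile) is presentation only.
`LengthSample` rejects non-positive lengths by default — measured objects
have positive length — and admits zeros only behind an explicit `allow_zero`
flag used for per-initiator-site bookkeeping, where empty sites belong in
Eq. 1's denominator.

The Poisson MLE for an untruncated histogram is the weighted mean. For
zero-truncated data the likelihood equation λ/(1 − e^(−λ)) = m is solved by a
bracketed Brent solve to 1e-8 (the left side is increasing from 1, so [ε, m]
always brackets). A truncated sample with mean ≤ 1 sits on the λ → 0
boundary and is reported as non-converged rather than returned silently.
Both truncated and untruncated fitting are exposed because the original
histogram fits do not state which was used; truncation is the package default
for surface assays (zero-label filaments are invisible).

## Photobleaching step counting

Traces are synthesized as descending staircases: n fluorophores, unit drops
at cumulative exponential dwells (memoryless single-fluorophore bleaching),
Gaussian noise, uniform camera grid at 3.88 Hz. Ground truth rides along in
the trace metadata.

The counter replaces by-eye counting with three explicit stages:

1. **Segmentation** — exact optimal-partitioning dynamic program for
   piecewise-constant least squares with per-segment penalty
   2·σ̂²·ln(n_frames), σ̂ the median-absolute-deviation of successive
   differences (robust to the steps themselves).
2. **Merging** — boundaries whose level drop is upward (blinking) or smaller
   than `min_step` (default 3σ̂) are removed iteratively, weakest first, so
   the fitted plateaus are strictly decreasing.
3. **Quantization** — plateau drops are divided by a unit step height and the
   count is the quantized total fall, round((first − last plateau)/unit).
   The unit is estimated per trace from the observed drops or, preferably,
   pooled across a batch (`count_steps_batch`), the standard single-molecule
   calibration of unitary fluorophore intensity.

Stage 3 is why `n_steps` may exceed the number of distinct change points: at
3.88 Hz with multi-second dwells, two bleach events fall within one
inter-frame gap often enough (≈ Δt/2τ per gap) that any one-step-per-change-
point counter caps well below 95% exact recovery at n = 10. Quantizing the
total fall makes the count insensitive to both hidden double drops and
spurious intermediate boundaries. Measured on the synthetic grid (200 traces
per cell, 3 s mean dwell, 80 s duration), exact recovery is ≥ 95% for
SNR ≥ 5 up to 10 fluorophores; SNR 3 is below the design point of the 3σ̂
step filter and is reported, not asserted. The whole pipeline is
scale-invariant: multiplying intensities and `min_step` by a constant changes
nothing.

What the synthetic traces do not model: EMCCD gain statistics, drift,
background slopes, and non-exponential photophysics. Recovery rates here
bound algorithmic error only, not camera physics.

## Elastic-rod mechanics

Constructs are discretized one node per base step (0.34 nm), coarse-grained
by an integer factor (series/harmonic-mean stiffness pooling) only when a rod
would exceed 2000 nodes. Element stiffnesses: duplex 230 pN·nm², DX regions
2 × 230 (two parallel helices, ignoring the parallel-axis offset;
configurable), inter-tile nicks 230/100 per the hundredfold softening rule,
single-stranded ends and loops kBT × 1 nm (a very soft bending element — the
modified freely-jointed-chain parameters this stands in for are not printed,
so the softest sensible WLC element is used instead). 230/4.114 ≈ 55.9 nm
reproduces the canonical duplex persistence length at 298 K.

RMSF is computed by normal-mode analysis of the transverse bending energy:
the discrete curvature Hessian (node stiffness = harmonic mean of the two
adjacent elements), with the two rigid-body modes (translation, rotation)
deflated exactly via an orthonormal complement — thresholding eigenvalues is
not safe here because the softest bending modes of a 1000-node rod are
numerically tiny. Each remaining mode receives kBT of energy per
equipartition and the two independent transverse directions are summed:
RMSF_i = √(2·kBT·[K⁺]_ii). Stretching (1100 pN) and torsion (460 pN·nm²) are
stored but excluded from the default RMSF; for slender rods transverse
bending dominates the soft spectrum.

The tests cross-check this spectral route against direct equilibrium sampling
of the same quadratic energy (independent Hessian assembly, rigid-subspace
penalty, Cholesky sampling, empirical variances) to within 5% on ≤ 50-node
rods, and assert the qualitative structure: free ends floppiest, maximum RMSF
monotone in filament length, dsDNA(24) ≤ monomer ≤ I-A-B ≤ I-[A-B]₅ ≤
I-[A-B]₁₀. Absolute RMSF magnitudes for long filaments are large because the
model is a linear free-free rod with no excluded volume or surface
attachment; only orderings and ratios are meaningful, and no reference
numeric RMSF values are available to compare against.

Relative compliance is k_b(dsDNA24)/k_b(rod) with k_b ∝ B_eff/L^exponent and
B_eff the length-weighted harmonic mean of element stiffness. The prose
definition of the source ("decreases inversely proportional to its length")
suggests exponent 1, while beam theory gives exponent 3 for a point-load
spring constant; both are implemented, exponent 3 is the default, and every
reported ordering holds under either.

## Synthetic data: what it does and does not emulate

The AFM emulation adds Gaussian length noise (default 8 nm), optional tip
broadening, and a 10 nm detection floor. These defaults are plausible
instrument-scale values chosen once — the study's actual measurement error is
not reported — so tests that pass under them demonstrate pipeline
correctness, not instrument realism. Measured-PDI inflation by length noise
is qualitative only. The trace generator covers exponential bleaching on an
ideal camera; see above for what that excludes. Sequence fixtures satisfy
every printed complementarity and segment-placement fact, but are not the
(unpublished) laboratory sequences.

## Problem sizes and numerical conventions

Simulations use 10⁴ initiator sites (the scale at which closed-form
comparisons resolve to ~1–2%), 4 × 10⁵ monomer units for the thermal control
(≈ 4000 chains, putting the Flory PDI estimate's sampling noise near 0.03),
200 traces per photobleaching grid cell, and ≤ 50-node rods for the sampling
oracle. All randomness flows through `numpy.random.default_rng` seeds;
populations carry their generator state so re-feeding continues the same
stream; the pipeline derives per-stage substreams from one global seed via
`SeedSequence`, making manifests byte-reproducible.
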