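# Methods

## Model

An F2 individual is the union of two independent F1 gametes. Over an ordered
triple of biallelic loci the eight gamete types pair into four *sister*
classes — a gamete and its allelic complement — assumed equally frequent
(no selection, drift, migration or mutation):

| class | dominant notation | codominant notation | frequency |
|-------|-------------------|---------------------|-----------|
| 1     | ABC / abc         | 111 / 000           | q1        |
| 2     | Abc / aBC         | 100 / 011           | q2        |
| 3     | ABc / abC         | 110 / 001           | q3        |
| 4     | AbC / aBc         | 101 / 010           | q4        |

with `2(q1+q2+q3+q4) = 1`. All estimation is per triple and complete-case:
an individual missing any of the three calls is excluded from that triple's
tally (how missing calls should be handled is genuinely open; complete-case
is the simplest choice that leaves the class frequencies unbiased).

### Dominant triples: the ELS estimator

Only seven phenotype classes are informative. Their expectations are

    Q1 = q1²                  (aabbcc)
    Q2 = q3² + 2 q1 q3        (aabbC_)       Q5 = Q2 + Q   (A_B_cc)
    Q3 = q4² + 2 q1 q4        (aaB_cc)       Q6 = Q3 + Q   (A_bbC_)
    Q4 = q2² + 2 q1 q2        (A_bbcc)       Q7 = Q4 + Q   (aaB_C_)

where `Q = 2(q2q3 + q2q4 + q3q4)`. The triple-dominant class `A_B_C_` mixes
all eight zygote configurations and is tallied only for the sum-to-one
invariant. Because the q's sum to 0.5, the observed frequencies obey

    Q1 + Q5 + Q6 + Q7 = 0.25 + 2Q,

so `Q` can be read off the data before any gamete estimate exists. Each
single-dominant class frequency has two estimates — the direct tally `Q̂k`
and the complement `Q̂k# = Q̂(k+3) − Q` — combined as `Q*k = (Q̂k + Q̂k#)/2`
(equal weights carry the most information; a magnitude-proportional
weighting is available via `weight_mode="proportional"`). Degenerate
samples fall back to whichever estimate is usable (`Q̂k# ≤ 0` → use `Q̂k`;
`Q̂k = 0` with `Q̂k# > 0` → use `Q̂k#`).

Given a candidate `q1`, the expectation step inverts the combined classes in
closed form:

    q̂3 = √(Q*2 + q1²) − q1,   q̂4 = √(Q*3 + q1²) − q1,   q̂2 = √(Q*4 + q1²) − q1

(the weight rules keep every `Q*k ≥ 0`, so the radicand is at least `q1²`
and the estimates are automatically non-negative). The least-square step
searches `q1` on a ±Δ walk started at `√Q̂1`: a move is accepted when it
lowers

    S²(q1) = Σ_{i=1..7} (Q̂i − E[Qi])²,

the first move tries the upward direction, and the walk ends when
`S² ≤ t`, when neither direction improves (a local minimum of the Δ-grid),
or at `max_iter`. Defaults: Δ = 1e-4 (also the resolution of the estimate),
t = 1e-6 on the squared-frequency scale, max_iter = 10 000.

Two design choices here departed from the construction as it is usually
written, both after measurement rather than taste:

1. **The i = 1 residual is part of S².** The triple-recessive class is the
   only term that pins `q1` directly. With it excluded, the objective
   depends on `q1` only through the mixture term `Q(q1)`, which is nearly
   flat for tightly linked coupling triples; the minimiser then has roughly
   three times the sampling SD of its own starting point `√Q̂1` (measured
   0.146 vs 0.048 at N = 100 on a 20 + 15 cM coupling triple) and map
   recovery collapses. Including the anchor restores a well-conditioned
   search.
2. **The expectation term stays anchored on the data.** Re-deriving `Q` from
   the current iterate and iterating that substitution to its fixed point
   makes every class-2..4 expectation match its combined target exactly, at
   which point `S²` no longer identifies `q1` at all. The implementation
   therefore evaluates every candidate `q1` with a single expectation step
   whose `Q` comes from the observed-frequency identity above. This also
   makes `S²(q1)` a deterministic function, so an exhaustive grid minimiser
   (`els_grid_oracle`) can and does check the line search point for point.

Known limitation: on *repulsion* triples (parental pair ≠ class 1, `q1`
small) the line search still inflates `q1` slightly (bias ≈ +0.03 at
N = 300 measured on a 20 + 15 cM repulsion triple) because the
mixture-matching residuals are asymmetric near the `q1 = 0` boundary. A
joint maximum-likelihood fit of the same seven class frequencies does
noticeably better there; the consequences for the benchmark are quantified
below. We keep the line-search construction because it *is* the method this
package implements, not a stand-in for one.

### Codominant triples: the BAT estimator

All fourteen complementary zygote-pair classes are observable, with
expectations `Pk = 2qk²`, `Pij = 4qiqj` and, for the two-heterozygote
classes, sums such as `P1234 = 4q1q2 + 4q3q4`. Two independent linear
combinations each form the perfect square `(qi + qj)²`:

    Q¹ij = (Pi + Pij + Pj)/2
    Q²ij = (Pi + P(two-het class) − P(complementary pair) + Pj)/2

merged with magnitude-proportional weights `a = Q̂¹/(Q̂¹+Q̂²)` (on exact
input both routes coincide, so the weights are irrelevant; a negative `Q̂²`,
possible in small samples, clamps to zero first, and `a = 1/2` guards the
all-zero case). Then

    q̂k = ½ [ (Σ_{j≠k} √Q̂kj − Σ_{j≠k} √(P̂j/2)) / 3 + √(P̂k/2) ],

an exact closed-form inverse: on noise-free class frequencies it returns
`q` to machine precision for *any* admissible vector (property-tested over
the whole simplex). The triple heterozygote `222` is tallied but unused. A
variant without the equal-sister-frequency assumption exists in the
literature; its equations are not in the main text we implement, so only
the name is reserved.

### From gamete frequencies to a map

Estimates are normalised (`pᵢ = q̂ᵢ / 2Σq̂`, so Σp = 0.5 exactly). Within a
triple, the largest class is the parental type and the smallest the
double-crossover type; the one locus at which the double-crossover gamete
(the member of its sister pair sharing two alleles with the parental
gamete) differs from the parental gamete is the middle locus. Phase is
coupling when the parental pair is class 1, otherwise the differing locus
is in repulsion with the outer pair. Ties within 1e-9 at either extremum
flag the triple ambiguous; it is excluded from averaging rather than
guessed. With D the double-crossover class and S1/S2 the classes differing
from the parental gamete only at the first/second outer locus,

    r(outer1, mid)    = 2 (p_S1 + p_D)
    r(mid, outer2)    = 2 (p_S2 + p_D)
    r(outer1, outer2) = 2 (p_S1 + p_S2),

twice the total frequency of classes recombinant in the interval. (Printed
formulations of the two canonical special cases swap the roles of p2 and p3
relative to their own worked arithmetic; this package follows the
arithmetic, which the role rule reproduces identically.) Note
`r(outer1, outer2)` excludes the double-crossover class by construction —
it equals `r1 + r2 − 2 r1 r2` on noise-free data, not `r1 + r2`.

Over n ≥ 3 markers, each pair gets one estimate per reference locus and
`θij` is their plain mean over all n−2 references (the literal averaging
rule; a `filter="linked"` option restricts references to triples passing
the 1:1:1:1 chi-square screen at α = 0.05, as in the real-data example).
The screen reconstructs counts on the `2·n_used` gametes the sample
carries, class frequency `2pᵢ` each, df = 3; the published per-triple
p-values could not be reproduced from any count construction we tried, so
no printed p-value is asserted — the construction here is simply declared.
Estimates above 0.5 are reported as computed (an optional cap at 0.5
exists). Locus order is the exhaustive minimum of the sum of adjacent
recombination fractions (SARF) over all permutations up to reversal, ties
broken lexicographically; exhaustive search is acceptable to 10 loci (the
study uses 6 → 360 distinct orders).

### Two-point EM baseline

The comparison method, reconstructed as the textbook F2 two-point EM since
the source text cites but does not reproduce it: the 16 ordered gamete-pair
configurations have probabilities `(1−r)/2` (parental) and `r/2`
(recombinant) per gamete; observed classes (9 codominant genotype classes,
4 dominant phenotype classes) mix configurations; the E-step distributes
each class over its configurations and the M-step sets r to the expected
recombinant-gamete fraction, constrained to [0, 0.5] (the constrained
M-step preserves the EM monotonicity guarantee, which is asserted on every
iteration). Convergence: |Δr| < 1e-8 or 1000 iterations, start r = 0.25.
With `phase_mode="unknown"` both phase models are fitted and the
higher-likelihood one returned — the statistically right treatment, and the
default for `TwoPointEM`.

## Simulator and study conditions

Meiosis is a point process with independent crossovers: each gamete starts
on a uniformly chosen parental strand and switches between adjacent loci
with probability `r(d) = (1 − e^(−2d/100))/2` — the Haldane map function,
the one consistent with "independent crossovers" (an identity map
`r = d/100` is available as a sensitivity option). Codominant loci segregate
1:2:1, dominant loci 3:1; "unknown phase" assigns each locus's dominant
allele to a random parent independently. The benchmark draws, per
replicate, five adjacent distances i.i.d. uniform from {10, 15, 20, 25, 30}
cM for 6 loci (redrawing per replicate; whether the original study fixed
one map per cell is not stated — redrawing averages over map
configurations, and per-fixed-map recovery varies by ±20 points around the
same mean), simulates N ∈ {100, 200, 300} individuals, estimates all
pairwise θ (ELS and BAT per-triple then reference-averaged; EM directly),
orders by SARF, and records exact-order recovery (up to reversal) and the
squared error of each adjacent-interval estimate. 100 replicates per cell;
all randomness flows from a single integer seed and identical configs give
bit-identical results.

**EM phase handling in the benchmark.** The published comparison's EM
recovery at unknown phase barely changes with sample size — the signature
of an EM that never adapts phase, since a likelihood-based phase choice
becomes reliable as N grows (we measure 85% recovery at N = 300 for the
adaptive EM versus a flat ~10% for a coupling-model-only EM). To reproduce
the comparison as performed, `run_benchmark` fits its EM rows under the
coupling model regardless of the data's phases (`em_phase_mode="coupling"`,
the default there and only there); the adaptive EM remains one option away.

## What the simulations do and do not show

The generator emulates idealised F2 meiosis: no crossover interference, no
segregation distortion, no genotyping error, equal sister-gamete
frequencies by construction, and missingness only if injected. Passing
benchmarks therefore speak to estimator behaviour under the model's own
assumptions — real data add error modes (dominant miscalls collapse
phenotype classes asymmetrically; interference shrinks double-crossover
classes below `r1·r2/2`, which would bias the middle-locus inference toward
ambiguity) that these tests do not probe.

Measured under the study conditions (100 replicates, fresh maps, seed 0):
ELS coupling N = 100 recovers ~91% of maps and BAT coupling N = 300 ~99%,
both consistent with the published study within its sampling noise. At
unknown phase and N = 300 the ELS pipeline recovers ~57–69% (seed
dependent) against a published 85.1%; a joint ML fit of the same class
frequencies reaches 83–87%, so the shortfall is a property of the
line-search construction on repulsion triples (see the limitation above),
not of the three-point strategy. The qualitative claims all hold: ELS
beats the phase-naive EM at unknown phase by a wide margin in both
recovery and per-interval MSE (~0.006 vs ~0.06 at N = 200), coupling beats
unknown phase for every estimator, and every coupling-phase recovery rate
exceeds 80% at N = 200.

## Numerical conventions

- Frequencies clamp at zero where sampling noise drives a radicand or a
  closed-form estimate negative; clamping is flagged, never silent.
- `q1` is confined to [0, 0.5]; `√0` is taken as a legitimate start when
  the triple-recessive class is empty.
- Tie-breaks: the line search tries +Δ first; the grid oracle and the SARF
  search break ties toward the smallest value/lexicographically smallest
  order; ambiguous triples (ties within 1e-9) are flagged, not resolved.
- File writes are atomic (temp file + rename).
- Dominant data read from codominant-coded files merge the B homozygote
  into the heterozygote class (B → H), matching how such conversions are
  made in practice; codes are stored as 0/1/2 with −1 for missing.
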