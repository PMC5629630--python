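# trigamete

Three-point gamete-frequency estimation and recombination mapping for F2
populations.

## The problem

In an F2 intercross, dominant markers in *repulsion* phase (dominant alleles
on opposite parental chromosomes) carry almost no two-point linkage
information: standard two-point EM cannot tell a repulsion heterozygote from
a coupling one, so maps built from dominant markers fall apart into two
complementary halves. Three-locus *gamete* analysis restores the missing
information. An F2 individual is the union of two F1 gametes; over an
ordered locus triple the eight gamete types form four sister pairs
(`ABC/abc`, `Abc/aBC`, `ABc/abC`, `AbC/aBc`) with frequencies `q1..q4`
constrained by `2(q1+q2+q3+q4) = 1`. Once the `q`'s are known, the rarest
class identifies the double-crossover type (hence the middle locus and the
phase), and every pairwise recombination fraction follows as twice the total
frequency of the classes recombinant in that interval.

This package implements, as scikit-learn-style estimators:

- **`ELSGameteEstimator`** — expectation–least-square estimation of `q1..q4`
  from *dominant* triples. The seven informative phenotype classes have
  expectations `Q1 = q1²`, `Q2 = q3² + 2q1q3`, …, `Q5 = Q2 + Q` with
  `Q = 2(q2q3 + q2q4 + q3q4)`. Given `q1`, inverting `Q2..Q4` is closed-form;
  `q1` itself is found by a ±Δ line search minimising the squared discrepancy
  `S²(q1) = Σᵢ (Q̂ᵢ − E[Qᵢ])²` between observed and expected class
  frequencies.
- **`BATGameteEstimator`** — closed-form binomial analysis of three-point
  gametes for *codominant* triples: the fourteen complementary zygote-pair
  classes assemble into perfect squares `(qᵢ + qⱼ)²` by two independent
  routes, and square roots recover each `qₖ` exactly, without iteration.
- **`TwoPointEM`** — the textbook F2 two-point EM recombination-fraction
  estimator (9-class codominant / 4-class dominant likelihoods), the
  comparison baseline.
- **`LinkageMapper`** — the full pipeline: per-triple estimation,
  normalisation (`pᵢ = q̂ᵢ / 2Σq̂`), order/phase inference, triple
  recombination fractions, averaging over reference loci
  (`θᵢⱼ = (1/(n−2)) Σₖ rᵢⱼₖ`), a 1:1:1:1 chi-square linkage screen, and
  exhaustive minimum-SARF locus ordering.
- **`simulate_f2` / `run_benchmark`** — an F2 meiosis simulator (independent
  crossovers, Haldane map function) and the recovery-rate / MSE comparison
  study design.

## Worked example

The package reproduces the published three-point arithmetic for four linked
dominant loci (1, 2, 3, 5) typed in 333 F2 mice. The estimated, normalised
gamete frequencies of the four triples ship as a fixture:

```python
import numpy as np
from trigamete import table3_fixture
from trigamete.mapping import analyze_triple, pairwise_theta

results = {t: analyze_triple(p) for t, p in table3_fixture().items()}
res = results[("1", "2", "3")]
print(res.ordered_loci, res.phase)
print(round(res.r_outer1_mid, 5), round(res.r_mid_outer2, 5),
      round(res.r_outer1_outer2, 5))

theta = pairwise_theta(list(results.values()), ["1", "2", "3", "5"])
print(theta.to_frame().round(6))
```

prints

```
('2', '1', '3') coupling
0.39327 0.36172 0.41034
          1         2         3         5
1  0.000000  0.387164  0.349396  0.377323
2  0.387164  0.000000  0.390506  0.416221
3  0.349396  0.390506  0.000000  0.436782
5  0.377323  0.416221  0.436782  0.000000
```

Reading: in triple (1,2,3) the most frequent class is `abc/ABC` (parental,
so the three loci are in coupling) and the rarest is `Abc/aBC`, whose
distinguishing locus — locus 1 — must be the middle one, giving the order
2–1–3. The recombination fraction between loci 2 and 1 is then
2(0.086162 + 0.110472) = 0.39327, and each pairwise θ is the mean of the two
triple-based estimates that contain the pair (e.g.
θ₁₂ = (0.393268 + 0.38106)/2 = 0.387164).

A command-line interface covers the same ground on genotype files
(MAPMAKER/EXP-style `.raw` or TSV):

```bash
trigamete --seed 7 simulate --loci 6 --type dominant --phase coupling --n 300 --out pop.raw
trigamete els --in pop.raw --out gametes.tsv
trigamete map --in pop.raw --method els --out-theta theta.tsv --out-order order.txt
trigamete benchmark --config bench.yaml --out bench.tsv
```

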