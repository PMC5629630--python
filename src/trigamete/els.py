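"""Expectation-least-square (ELS) estimation of dominant three-locus gamete
frequencies in an F2 population.

With dominant markers only four of the eight three-locus phenotype classes
identify gametes directly.  Writing ``Q1..Q7`` for the expected frequencies
of the seven informative phenotypes (triple-recessive, the three
single-dominant and the three double-dominant classes), the forward model is

    Q1 = q1^2
    Q2 = q3^2 + 2 q1 q3        (aabbC_)
    Q3 = q4^2 + 2 q1 q4        (aaB_cc)
    Q4 = q2^2 + 2 q1 q2        (A_bbcc)
    Q5 = Q2 + Q,  Q6 = Q3 + Q,  Q7 = Q4 + Q,   Q = 2(q2 q3 + q2 q4 + q3 q4)

where q1..q4 are the sister-pair gamete frequencies (q1 the parental-type
abc/ABC pair).  Inverting Q2..Q4 for fixed q1 is closed-form (a square-root
per class); q1 itself is found by a one-dimensional +-Delta line search
minimising the squared discrepancy

    S^2(q1) = sum_{i=2..7} (Qhat_i - E[Q_i])^2 .

The double-dominant classes supply a second, noise-reducing estimate of
Q2..Q4 via Q#k = Qhat_{k+3} - Q; both estimates are averaged (equal weights
by default).  Because sister-pair frequencies sum to 0.5, the observed
frequencies satisfy Q1 + Q5 + Q6 + Q7 = 0.25 + 2Q, which supplies Q for the
expectation step directly from the data; the expected double-dominant
frequencies are then recomputed from the gamete estimates implied by each
candidate q1, so the line search balances the implied mixture term against
the observed one.

Two numerical choices matter and are deliberate (see docs/methods.md):

* S^2 runs over all seven informative classes, i = 1..7.  The i = 1 residual
  (Qhat1 - q1^2)^2 is what anchors the search: without it the objective
  depends on q1 only through the nearly-flat mixture term and the minimiser
  has a markedly larger sampling variance than its own starting point.
* The expectation step keeps Q anchored on the observed-frequency identity
  rather than re-deriving it from the current iterate: iterating that
  substitution to its fixed point makes S^2 asymptotically flat in q1 and
  destroys the identification altogether.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator

from .data_model import (
    DOMINANT,
    MISSING,
    DominantPhenotypeFreqs,
    EmptyDataError,
    GameteFreqs,
    GenotypeMatrix,
)

__all__ = [
    "ELSConfig",
    "ELSGameteEstimator",
    "tally_dominant_phenotypes",
    "complement_and_combine",
    "els_estimate",
    "els_grid_oracle",
    "expected_dominant_freqs",
]


@dataclass
class ELSConfig:
    """Tuning parameters of the ELS line search.

    delta
        Step size of the q1 search, also the resolution of the estimate.
    tol
        Stop when S^2 (a squared-frequency quantity) falls below this.
    max_iter
        Cap on evaluated line-search steps.
    weight_mode
        'equal' averages the direct and complement estimates of Q2..Q4;
        'proportional' weights each by its own magnitude.
    """

    delta: float = 1e-4
    tol: float = 1e-6
    max_iter: int = 10_000
    weight_mode: str = "equal"

    def __post_init__(self) -> None:
        if self.delta <= 0 or self.tol <= 0 or self.max_iter < 1:
            raise ValueError("delta and tol must be positive, max_iter >= 1")
        if self.weight_mode not in ("equal", "proportional"):
            raise ValueError(f"unknown weight_mode: {self.weight_mode!r}")


# map from the 3-bit dominant/recessive pattern (d_a*4 + d_b*2 + d_c) to the
# phenotype-class index 0..7 (Q1..Q8 ordering)
_PHENO_LUT = np.array([0, 1, 2, 6, 3, 5, 4, 7], dtype=np.intp)


def expected_dominant_freqs(q) -> np.ndarray:
    """Exact phenotype-class frequencies Q1..Q8 implied by gamete freqs q1..q4."""
    q1, q2, q3, q4 = (float(v) for v in q)
    Q = 2.0 * (q2 * q3 + q2 * q4 + q3 * q4)
    out = np.empty(8)
    out[0] = q1 * q1
    out[1] = q3 * q3 + 2 * q1 * q3
    out[2] = q4 * q4 + 2 * q1 * q4
    out[3] = q2 * q2 + 2 * q1 * q2
    out[4] = out[1] + Q
    out[5] = out[2] + Q
    out[6] = out[3] + Q
    out[7] = 1.0 - out[:7].sum()
    return out


def tally_dominant_calls(calls3: np.ndarray) -> np.ndarray:
    """Phenotype-class relative frequencies (8,) from complete-case calls (n, 3)."""
    n = calls3.shape[0]
    if n == 0:
        raise EmptyDataError("no complete-case individuals at this triple")
    bits = (calls3 == DOMINANT).astype(np.intp)
    keys = bits[:, 0] * 4 + bits[:, 1] * 2 + bits[:, 2]
    counts = np.bincount(_PHENO_LUT[keys], minlength=8)
    return counts / n


def tally_dominant_phenotypes(
    matrix: GenotypeMatrix, triple: tuple[str, str, str]
) -> DominantPhenotypeFreqs:
    """Observed frequencies of the eight phenotype classes at a marker triple.

    Individuals with a missing call at any of the three markers are excluded
    (complete-case per triple).
    """
    if matrix.marker_type != "dominant":
        raise ValueError("tally_dominant_phenotypes requires dominant markers")
    sub = matrix.triple_calls(triple)
    return DominantPhenotypeFreqs(
        qhat=tally_dominant_calls(sub), n_used=sub.shape[0], locus_ids=tuple(triple)
    )


def _combine(qhat_k: float, qsharp_k: float, proportional: bool) -> float:
    # degenerate-weight rules: a=1,b=0 when Q# <= 0; a=0,b=1 when Qhat = 0
    if qsharp_k <= 0.0:
        return qhat_k
    if qhat_k == 0.0:
        return qsharp_k
    if proportional:
        return (qhat_k * qhat_k + qsharp_k * qsharp_k) / (qhat_k + qsharp_k)
    return 0.5 * (qhat_k + qsharp_k)


def complement_and_combine(
    Qhat: DominantPhenotypeFreqs, cfg: ELSConfig | None = None
) -> tuple[float, float, float]:
    """Combined estimates (Q*2, Q*3, Q*4) of the single-dominant class
    frequencies, averaging the direct tallies with the complements
    Q#k = Qhat_{k+3} - Q, where Q = (Qhat1 + Qhat5 + Qhat6 + Qhat7 - 0.25)/2
    is the double-crossover-mixture term recovered from the observed
    frequencies."""
    cfg = cfg or ELSConfig()
    prop = cfg.weight_mode == "proportional"
    qh = Qhat.qhat
    Q = (qh[0] + qh[4] + qh[5] + qh[6] - 0.25) / 2.0
    return tuple(_combine(float(qh[k]), float(qh[k + 3]) - Q, prop) for k in (1, 2, 3))


def _bootstrap_EQ(qh: np.ndarray) -> float:
    """Observed-frequency estimate of the mixture term Q = 2(q2q3+q2q4+q3q4).

    Sister-pair frequencies sum to 0.5, so Q1+Q5+Q6+Q7 = 0.25 + 2Q; this
    recovers Q before any gamete estimates exist (the iteration-0 bootstrap
    of the expectation step).
    """
    return (float(qh[0]) + float(qh[4]) + float(qh[5]) + float(qh[6]) - 0.25) / 2.0


def _s2_profile(
    qh: np.ndarray, q1: float, proportional: bool, EQ_in: float
) -> tuple[float, float, float, float]:
    """Evaluate S^2 at a candidate q1 with one expectation step.

    ``EQ_in`` is the current estimate of the double-dominant mixture term Q
    used to form the complements Q#k = Qhat_{k+3} - Q; the expected class
    frequencies are then recomputed from the implied gamete estimates.  With
    EQ_in held fixed, S^2 is a deterministic function of q1 alone, anchored
    by the triple-recessive residual (Qhat1 - q1^2)^2 and shaped by the
    mixture-term residuals (c - EQ_out(q1))^2 with EQ_out monotone in q1.
    Returns (S2, q2, q3, q4).
    """
    Qh1, Qh2, Qh3, Qh4, Qh5, Qh6, Qh7 = (float(v) for v in qh[:7])
    q1sq = q1 * q1
    Qs2 = _combine(Qh2, Qh5 - EQ_in, proportional)
    Qs3 = _combine(Qh3, Qh6 - EQ_in, proportional)
    Qs4 = _combine(Qh4, Qh7 - EQ_in, proportional)
    # Q*k >= 0 by the weight rules, so the radicand >= q1^2 and q_k >= 0
    q3 = math.sqrt(max(Qs2 + q1sq, 0.0)) - q1
    q4 = math.sqrt(max(Qs3 + q1sq, 0.0)) - q1
    q2 = math.sqrt(max(Qs4 + q1sq, 0.0)) - q1
    EQ_out = 2.0 * (q2 * q3 + q2 * q4 + q3 * q4)
    E2 = q3 * q3 + 2 * q1 * q3
    E3 = q4 * q4 + 2 * q1 * q4
    E4 = q2 * q2 + 2 * q1 * q2
    S2 = (
        (Qh1 - q1sq) ** 2
        + (Qh2 - E2) ** 2
        + (Qh3 - E3) ** 2
        + (Qh4 - E4) ** 2
        + (Qh5 - E2 - EQ_out) ** 2
        + (Qh6 - E3 - EQ_out) ** 2
        + (Qh7 - E4 - EQ_out) ** 2
    )
    return S2, q2, q3, q4


def els_estimate(
    Qhat: DominantPhenotypeFreqs, cfg: ELSConfig | None = None
) -> tuple[GameteFreqs, dict]:
    """Estimate gamete frequencies q1..q4 from dominant phenotype frequencies.

    q1 starts at sqrt(Qhat1) and walks in +-delta steps, accepting moves that
    reduce S^2; the first move tries the upward direction.  The walk stops
    when S^2 <= tol, when neither direction improves (a local minimum of the
    delta-grid), or at max_iter.  Returns the gamete frequencies and an info
    dict with keys S2, n_iter, converged.
    """
    cfg = cfg or ELSConfig()
    prop = cfg.weight_mode == "proportional"
    qh = np.asarray(Qhat.qhat, dtype=float)
    if qh[0] < 0:
        raise ValueError("Qhat1 must be non-negative")

    EQ_in = _bootstrap_EQ(qh)
    q1 = min(math.sqrt(max(float(qh[0]), 0.0)), 0.5)
    best_S2, q2, q3, q4 = _s2_profile(qh, q1, prop, EQ_in)
    best = (q1, q2, q3, q4)
    direction = 1.0
    rejected: set[float] = set()
    n_iter = 0
    while n_iter < cfg.max_iter and best_S2 > cfg.tol:
        q1_new = min(max(best[0] + direction * cfg.delta, 0.0), 0.5)
        if q1_new == best[0]:  # pinned at a boundary
            rejected.add(direction)
            if len(rejected) == 2:
                break
            direction = -direction
            continue
        n_iter += 1
        S2_new, q2, q3, q4 = _s2_profile(qh, q1_new, prop, EQ_in)
        if S2_new < best_S2:
            best_S2 = S2_new
            best = (q1_new, q2, q3, q4)
            rejected.clear()
        else:
            rejected.add(direction)
            if len(rejected) == 2:
                break
            direction = -direction

    freqs = GameteFreqs(q=np.array(best), locus_ids=Qhat.locus_ids)
    info = {"S2": best_S2, "n_iter": n_iter, "converged": bool(best_S2 <= cfg.tol)}
    return freqs, info


def els_grid_oracle(
    Qhat: DominantPhenotypeFreqs,
    step: float = 1e-4,
    weight_mode: str = "equal",
) -> float:
    """Exhaustive grid minimiser of S^2 over q1 in {0, step, ..., 0.5}.

    Evaluates the same fixed-point S^2 profile as the line search at every
    grid point and returns the argmin (ties broken toward the smallest q1).
    Intended as an independent check of the line search, not for routine use.
    """
    if step <= 0:
        raise ValueError("step must be positive")
    qh = np.asarray(Qhat.qhat, dtype=float)
    prop = weight_mode == "proportional"
    EQ_in = _bootstrap_EQ(qh)
    grid = np.arange(0.0, 0.5 + step / 2, step)
    best_q1, best_S2 = 0.0, math.inf
    for g in grid:
        S2 = _s2_profile(qh, float(g), prop, EQ_in)[0]
        if S2 < best_S2:
            best_S2, best_q1 = S2, float(g)
    return best_q1


class ELSGameteEstimator(BaseEstimator):
    """Scikit-learn style wrapper around the ELS gamete-frequency estimator.

    Parameters mirror :class:`ELSConfig`.  ``fit(X)`` expects an
    (n_individuals, 3) integer array of dominant calls at an ordered marker
    triple (0 = recessive class, 2 = dominant phenotype, -1 = missing);
    rows with a missing call are dropped.

    Attributes
    ----------
    q_ : ndarray (4,)
        Estimated sister-pair gamete frequencies q1..q4.
    phenotype_freqs_ : DominantPhenotypeFreqs
        Observed class frequencies the fit was computed from.
    S2_, n_iter_, converged_, n_used_
        Line-search diagnostics and complete-case sample size.
    """

    def __init__(
        self,
        delta: float = 1e-4,
        tol: float = 1e-6,
        max_iter: int = 10_000,
        weight_mode: str = "equal",
    ):
        self.delta = delta
        self.tol = tol
        self.max_iter = max_iter
        self.weight_mode = weight_mode

    def _config(self) -> ELSConfig:
        return ELSConfig(
            delta=self.delta, tol=self.tol, max_iter=self.max_iter,
            weight_mode=self.weight_mode,
        )

    def fit(self, X, y=None):
        X = np.asarray(X)
        if X.ndim != 2 or X.shape[1] != 3:
            raise ValueError("X must be (n_individuals, 3) dominant calls")
        keep = (X != MISSING).all(axis=1)
        sub = X[keep]
        qhat = DominantPhenotypeFreqs(
            qhat=tally_dominant_calls(sub), n_used=int(sub.shape[0])
        )
        freqs, info = els_estimate(qhat, self._config())
        self.phenotype_freqs_ = qhat
        self.n_used_ = qhat.n_used
        self.q_ = freqs.q
        self.S2_ = info["S2"]
        self.n_iter_ = info["n_iter"]
        self.converged_ = info["converged"]
        return self
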