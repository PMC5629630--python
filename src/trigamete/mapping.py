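"""From gamete frequencies to recombination fractions and locus order.

Within a triple, the most frequent sister-pair class is the parental type
and the least frequent is the double-crossover type; the single locus at
which the double-crossover gamete differs from the parental gamete is the
middle locus, which simultaneously fixes the within-triple order and the
linkage phase (coupling when the parental pair is abc/ABC, otherwise the
differing locus is in repulsion with the outer pair).  With the parental
class P, the double-crossover class D, and S1/S2 the classes differing from
P only at the first/second outer locus, the three recombination fractions
are

    r(outer1, mid)    = 2 (p_S1 + p_D)
    r(mid, outer2)    = 2 (p_S2 + p_D)
    r(outer1, outer2) = 2 (p_S1 + p_S2)

i.e. twice the total frequency of classes recombinant in the interval.  Over
n >= 3 markers, each pair (i, j) receives one triple-based estimate r_ijk per
reference locus k; the pairwise estimate is their mean,
theta_ij = (1/(n-2)) * sum_k r_ijk.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import replace

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator

from .data_model import (
    CLASS_PATTERNS,
    DegenerateInputError,
    GameteFreqs,
    NormalizedGameteFreqs,
    ThetaMatrix,
    TripleResult,
)

__all__ = [
    "normalize",
    "infer_order_phase",
    "triple_recomb_fractions",
    "analyze_triple",
    "linkage_chisq",
    "pairwise_theta",
    "order_map",
    "LinkageMapper",
    "AmbiguousTripleError",
]

_TIE_TOL = 1e-9


class AmbiguousTripleError(ValueError):
    """Order/phase could not be resolved (tied class frequencies)."""


def normalize(q: GameteFreqs) -> NormalizedGameteFreqs:
    """Rescale gamete frequencies so they sum to 0.5 exactly."""
    total = float(q.q.sum())
    if total <= 0:
        raise DegenerateInputError("all gamete frequency estimates are zero")
    return NormalizedGameteFreqs(p=q.q / (2.0 * total), locus_ids=q.locus_ids)


def _role_class(parental: int, position: int) -> int:
    """0-based index of the class differing from the parental gamete only at
    `position` (0, 1 or 2 along the ordered triple)."""
    vp = CLASS_PATTERNS[parental]
    for k in range(4):
        if k == parental:
            continue
        x = vp ^ CLASS_PATTERNS[k]
        w = int(x.sum())
        diff = int(np.argmax(x)) if w == 1 else int(np.argmin(x))
        if diff == position:
            return k
    raise AssertionError("unreachable: role class always exists")


def infer_order_phase(p: NormalizedGameteFreqs) -> TripleResult:
    """Infer within-triple locus order and linkage phase from class frequencies.

    The parental class is the argmax of p, the double-crossover class the
    argmin.  Ties within 1e-9 set the ambiguous flag instead of raising.
    """
    arr = np.asarray(p.p, dtype=float)
    order_desc = np.argsort(arr)[::-1]
    parental = int(order_desc[0])
    dco = int(order_desc[-1])
    tied = (
        arr[parental] - arr[int(order_desc[1])] < _TIE_TOL
        or arr[int(order_desc[-2])] - arr[dco] < _TIE_TOL
    )
    if tied:
        return TripleResult(
            locus_ids=p.locus_ids, ordered_loci=None, phase="ambiguous",
            parental_class=None, double_co_class=None, ambiguous=True,
        )
    x = CLASS_PATTERNS[parental] ^ CLASS_PATTERNS[dco]
    w = int(x.sum())
    # the double-CO gamete shares two alleles with the parental gamete: if the
    # listed representative differs at two positions its sister differs at one
    mid_pos = int(np.argmax(x)) if w == 1 else int(np.argmin(x))
    outers = [p.locus_ids[i] for i in range(3) if i != mid_pos]
    ordered = (outers[0], p.locus_ids[mid_pos], outers[1])
    phase = "coupling" if parental == 0 else "repulsion"
    return TripleResult(
        locus_ids=p.locus_ids, ordered_loci=ordered, phase=phase,
        parental_class=parental + 1, double_co_class=dco + 1,
    )


def triple_recomb_fractions(
    result: TripleResult, p: NormalizedGameteFreqs
) -> TripleResult:
    """Fill the three recombination fractions of an order-resolved triple."""
    if result.ambiguous or result.ordered_loci is None:
        raise AmbiguousTripleError(
            f"order undetermined for triple {result.locus_ids}: tied frequencies"
        )
    arr = np.asarray(p.p, dtype=float)
    parental = result.parental_class - 1
    dco = result.double_co_class - 1
    o1, mid, o2 = result.ordered_loci
    pos = {name: i for i, name in enumerate(p.locus_ids)}
    s1 = _role_class(parental, pos[o1])
    s2 = _role_class(parental, pos[o2])
    return replace(
        result,
        r_outer1_mid=2.0 * (arr[s1] + arr[dco]),
        r_mid_outer2=2.0 * (arr[s2] + arr[dco]),
        r_outer1_outer2=2.0 * (arr[s1] + arr[s2]),
    )


def analyze_triple(p: NormalizedGameteFreqs) -> TripleResult:
    """Order/phase inference plus recombination fractions in one step."""
    result = infer_order_phase(p)
    if result.ambiguous:
        return result
    return triple_recomb_fractions(result, p)


def linkage_chisq(p: NormalizedGameteFreqs, n_used: int) -> tuple[float, float]:
    """Goodness-of-fit of the four gamete classes against a 1:1:1:1 ratio.

    Counts are reconstructed on the 2*n_used gametes carried by the sample
    (class frequency among gametes is 2*p_i), df = 3.  A small p-value is
    evidence of linkage within the triple.
    """
    if n_used <= 0:
        raise ValueError("n_used must be positive")
    counts = np.rint(2.0 * n_used * 2.0 * np.asarray(p.p, dtype=float))
    stat, pval = stats.chisquare(counts, f_exp=np.full(4, counts.sum() / 4.0))
    return float(stat), float(pval)


def pairwise_theta(
    results: list[TripleResult],
    markers: list[str],
    filter: str = "all",
    screen_pvalues: dict | None = None,
    alpha: float = 0.05,
    cap_half: bool = False,
) -> ThetaMatrix:
    """Average the triple-based recombination fractions into a pairwise matrix.

    With ``filter='linked'``, a triple contributes only if its 1:1:1:1
    chi-square p-value (keyed by frozenset of its loci in
    ``screen_pvalues``) is below ``alpha``, i.e. the triple shows linkage.
    Ambiguous triples never contribute.  Pairs with no eligible reference
    are NaN.  ``cap_half`` truncates estimates at 0.5.
    """
    if filter not in ("all", "linked"):
        raise ValueError(f"unknown filter: {filter!r}")
    if filter == "linked" and screen_pvalues is None:
        raise ValueError("filter='linked' requires screen_pvalues")
    m = len(markers)
    pos = {name: i for i, name in enumerate(markers)}
    total = np.zeros((m, m))
    count = np.zeros((m, m), dtype=int)
    for res in results:
        if res.ambiguous or res.ordered_loci is None:
            continue
        if filter == "linked":
            pv = screen_pvalues.get(frozenset(res.locus_ids))
            if pv is None or pv >= alpha:
                continue
        for pair, r in res.pair_fractions().items():
            a, b = (pos[x] for x in pair)
            if cap_half:
                r = min(r, 0.5)
            total[a, b] += r
            total[b, a] += r
            count[a, b] += 1
            count[b, a] += 1
    with np.errstate(invalid="ignore"):
        theta = np.where(count > 0, total / np.maximum(count, 1), np.nan)
    np.fill_diagonal(theta, 0.0)
    return ThetaMatrix(markers=list(markers), theta=theta, n_refs=count)


def order_map(theta: ThetaMatrix, loci: list[str] | None = None) -> list[str]:
    """Exhaustive minimum-SARF locus ordering.

    Searches all permutations (up to reversal) of the given loci and returns
    the order minimising the sum of adjacent recombination fractions; ties
    break to the lexicographically smallest order.  Limited to 10 loci.
    """
    loci = list(loci) if loci is not None else list(theta.markers)
    if len(loci) < 3:
        raise ValueError("ordering needs at least 3 loci")
    if len(loci) > 10:
        raise ValueError("exhaustive ordering limited to 10 loci")
    pos = {name: i for i, name in enumerate(theta.markers)}
    idx = [pos[x] for x in loci]
    sub = theta.theta[np.ix_(idx, idx)]
    missing = [
        (loci[i], loci[j])
        for i in range(len(loci))
        for j in range(i + 1, len(loci))
        if math.isnan(sub[i, j])
    ]
    if missing:
        raise ValueError(f"theta undefined for pairs: {missing}")

    best_order, best_sarf = None, math.inf
    for perm in itertools.permutations(range(len(loci))):
        if perm[0] > perm[-1]:  # each order once, up to reversal
            continue
        sarf = sum(sub[perm[i], perm[i + 1]] for i in range(len(perm) - 1))
        names = [loci[i] for i in perm]
        canonical = min(names, list(reversed(names)))
        if sarf < best_sarf - 1e-12 or (
            abs(sarf - best_sarf) <= 1e-12
            and (best_order is None or canonical < best_order)
        ):
            best_sarf, best_order = sarf, canonical
    return best_order


class LinkageMapper(BaseEstimator):
    """Full three-point mapping pipeline as a scikit-learn style estimator.

    ``fit(X)`` takes an (n_individuals, n_markers) integer call matrix
    (dominant codes for ``method='els'``, codominant for ``'bat'``; either
    for ``'em'``, stated via ``marker_type``) and produces the pairwise
    recombination-fraction matrix and the minimum-SARF locus order.

    Parameters
    ----------
    method : 'els', 'bat' or 'em'
        Triple-based gamete estimation (els/bat, averaged per reference
        locus) or direct two-point EM per pair.
    filter : 'all' or 'linked'
        Reference-loci filter for the theta averaging (triple chi-square
        screen at ``alpha``).
    marker_type : 'dominant' or 'codominant'
        Required for method='em'.
    em_phase_mode : 'unknown', 'coupling' or 'repulsion'
        Phase handling of the EM pairs; 'unknown' (default) fits both phase
        models per pair and keeps the likelier one.

    Attributes
    ----------
    theta_ : ThetaMatrix
    order_ : list of marker names or None if ordering failed
    triple_results_ : list of TripleResult (els/bat only)
    chisq_pvalues_ : dict mapping frozenset of loci to the screen p-value
    """

    def __init__(
        self,
        method: str = "els",
        filter: str = "all",
        alpha: float = 0.05,
        cap_half: bool = False,
        marker_type: str | None = None,
        em_phase_mode: str = "unknown",
        delta: float = 1e-4,
        tol: float = 1e-6,
        max_iter: int = 10_000,
        weight_mode: str = "equal",
    ):
        self.method = method
        self.filter = filter
        self.alpha = alpha
        self.cap_half = cap_half
        self.marker_type = marker_type
        self.em_phase_mode = em_phase_mode
        self.delta = delta
        self.tol = tol
        self.max_iter = max_iter
        self.weight_mode = weight_mode

    def fit(self, X, y=None, markers: list[str] | None = None):
        from .bat import BATGameteEstimator
        from .els import ELSGameteEstimator
        from .em import TwoPointEM

        X = np.asarray(X)
        if X.ndim != 2 or X.shape[1] < 3:
            raise ValueError("X must be (n_individuals, >=3 markers)")
        m = X.shape[1]
        names = list(markers) if markers is not None else [f"M{i+1}" for i in range(m)]
        self.markers_ = names

        if self.method == "em":
            if self.marker_type not in ("dominant", "codominant"):
                raise ValueError("method='em' requires marker_type")
            theta = np.full((m, m), np.nan)
            np.fill_diagonal(theta, 0.0)
            for i, j in itertools.combinations(range(m), 2):
                em = TwoPointEM(
                    marker_type=self.marker_type, phase_mode=self.em_phase_mode
                )
                em.fit(X[:, [i, j]])
                theta[i, j] = theta[j, i] = em.r_
            self.triple_results_ = []
            self.chisq_pvalues_ = {}
            self.theta_ = ThetaMatrix(
                markers=names, theta=theta,
                n_refs=np.ones((m, m), dtype=int) - np.eye(m, dtype=int),
            )
        elif self.method in ("els", "bat"):
            results, pvals = [], {}
            for tri in itertools.combinations(range(m), 3):
                sub = X[:, list(tri)]
                ids = tuple(names[k] for k in tri)
                try:
                    if self.method == "els":
                        est = ELSGameteEstimator(
                            delta=self.delta, tol=self.tol,
                            max_iter=self.max_iter, weight_mode=self.weight_mode,
                        ).fit(sub)
                    else:
                        est = BATGameteEstimator().fit(sub)
                    freqs = GameteFreqs(q=est.q_, locus_ids=ids)
                    p = normalize(freqs)
                except DegenerateInputError:
                    continue
                pvals[frozenset(ids)] = linkage_chisq(p, est.n_used_)[1]
                res = analyze_triple(p)
                results.append(res)
            self.triple_results_ = results
            self.chisq_pvalues_ = pvals
            self.theta_ = pairwise_theta(
                results, names, filter=self.filter,
                screen_pvalues=pvals, alpha=self.alpha, cap_half=self.cap_half,
            )
        else:
            raise ValueError(f"unknown method: {self.method!r}")

        try:
            self.order_ = order_map(self.theta_)
        except ValueError:
            self.order_ = None
        return self
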