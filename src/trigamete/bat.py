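"""Binomial analysis of three-point gametes (BAT): closed-form gamete
frequency estimation for codominant marker triples in F2.

With codominant markers every zygote class is observed.  The 27 three-locus
genotypes over codes {0, 1, 2} (0/1 the two parental homozygotes, 2 the
heterozygote) collapse into 14 complementary classes whose expected
frequencies are simple polynomials in the sister-pair gamete frequencies
q1..q4, e.g. P1 = f(111) + f(000) = 2 q1^2 and P12 = f(200) + f(211) = 4 q1 q2.
Two independent linear combinations of class frequencies each form the
perfect square (qi + qj)^2:

    Q1_ij = (Pi + Pij + Pj) / 2
    Q2_ij = (Pi + P(two-het class containing ij) - P(complement pair) + Pj) / 2

and are merged with magnitude-proportional weights.  Square roots of the six
Q_ij and of Pk/2 then give each q_k in closed form; no iteration is needed.
"""

from __future__ import annotations

import math

import numpy as np
from sklearn.base import BaseEstimator

from .data_model import (
    CODOMINANT_CLASS_NAMES,
    MISSING,
    CodominantClassFreqs,
    EmptyDataError,
    GameteFreqs,
    GenotypeMatrix,
)

__all__ = [
    "BATGameteEstimator",
    "tally_zygote_pairs",
    "bat_estimate",
    "expected_codominant_freqs",
]

# membership of each genotype (base-3 key over codes 0/1/2) in the 14 classes
_CLASS_MEMBERS = {
    "P1": [(1, 1, 1), (0, 0, 0)],
    "P2": [(1, 0, 0), (0, 1, 1)],
    "P3": [(1, 1, 0), (0, 0, 1)],
    "P4": [(1, 0, 1), (0, 1, 0)],
    "P12": [(2, 0, 0), (2, 1, 1)],
    "P13": [(1, 1, 2), (0, 0, 2)],
    "P14": [(1, 2, 1), (0, 2, 0)],
    "P23": [(0, 2, 1), (1, 2, 0)],
    "P24": [(1, 0, 2), (0, 1, 2)],
    "P34": [(2, 0, 1), (2, 1, 0)],
    "P1234": [(1, 2, 2), (0, 2, 2)],
    "P1324": [(2, 2, 1), (2, 2, 0)],
    "P1423": [(2, 1, 2), (2, 0, 2)],
    "P222": [(2, 2, 2)],
}

_CLASS_LUT = np.full(27, -1, dtype=np.intp)
for _idx, _name in enumerate(CODOMINANT_CLASS_NAMES):
    for _g in _CLASS_MEMBERS[_name]:
        _CLASS_LUT[_g[0] * 9 + _g[1] * 3 + _g[2]] = _idx
assert (_CLASS_LUT >= 0).all()


def expected_codominant_freqs(q) -> np.ndarray:
    """Exact zygote-pair class frequencies (14,) implied by gamete freqs q1..q4."""
    q1, q2, q3, q4 = (float(v) for v in q)
    return np.array([
        2 * q1 * q1, 2 * q2 * q2, 2 * q3 * q3, 2 * q4 * q4,
        4 * q1 * q2, 4 * q1 * q3, 4 * q1 * q4,
        4 * q2 * q3, 4 * q2 * q4, 4 * q3 * q4,
        4 * q1 * q2 + 4 * q3 * q4,
        4 * q1 * q3 + 4 * q2 * q4,
        4 * q1 * q4 + 4 * q2 * q3,
        2 * (q1 * q1 + q2 * q2 + q3 * q3 + q4 * q4),
    ])


def tally_zygote_calls(calls3: np.ndarray) -> np.ndarray:
    """Class relative frequencies (14,) from complete-case codominant calls (n, 3)."""
    n = calls3.shape[0]
    if n == 0:
        raise EmptyDataError("no complete-case individuals at this triple")
    keys = calls3[:, 0].astype(np.intp) * 9 + calls3[:, 1] * 3 + calls3[:, 2]
    counts = np.bincount(_CLASS_LUT[keys], minlength=14)
    return counts / n


def tally_zygote_pairs(
    matrix: GenotypeMatrix, triple: tuple[str, str, str]
) -> CodominantClassFreqs:
    """Observed frequencies of the 14 complementary zygote-pair classes.

    Complete-case per triple: individuals with any missing call are excluded.
    """
    if matrix.marker_type != "codominant":
        raise ValueError("tally_zygote_pairs requires codominant markers")
    sub = matrix.triple_calls(triple)
    return CodominantClassFreqs(
        freqs=tally_zygote_calls(sub), n_used=sub.shape[0], locus_ids=tuple(triple)
    )


# for each unordered gamete-class pair (i, j): the two-heterozygote class
# containing 4*qi*qj and the one-heterozygote class to subtract
_Q2_RULE = {
    (1, 2): ("P1234", "P34"),
    (1, 3): ("P1324", "P24"),
    (1, 4): ("P1423", "P23"),
    (2, 3): ("P1423", "P14"),
    (2, 4): ("P1324", "P13"),
    (3, 4): ("P1234", "P12"),
}


def _pairwise_Q(classes: CodominantClassFreqs) -> dict[tuple[int, int], float]:
    """Weighted binomial quantities Q_ij = (qi + qj)^2 for the six pairs."""
    out = {}
    for (i, j), (two_het, sub) in _Q2_RULE.items():
        Pi, Pj = classes[f"P{i}"], classes[f"P{j}"]
        q1_est = 0.5 * (Pi + classes[f"P{i}{j}"] + Pj)
        q2_est = 0.5 * (Pi + classes[two_het] - classes[sub] + Pj)
        q2_est = max(q2_est, 0.0)  # (qi+qj)^2 cannot be negative
        tot = q1_est + q2_est
        a = 0.5 if tot == 0.0 else q1_est / tot
        out[(i, j)] = a * q1_est + (1.0 - a) * q2_est
    return out


def bat_estimate(classes: CodominantClassFreqs) -> tuple[GameteFreqs, dict]:
    """Closed-form gamete frequencies q1..q4 from zygote-pair class frequencies.

    Each q_k combines the three square roots sqrt(Q_kj) = qk + qj with the
    homozygote corrections sqrt(P/2); negative results are clamped to zero
    (flagged in the info dict).
    """
    Q = _pairwise_Q(classes)
    sp = [math.sqrt(classes[f"P{k}"] / 2.0) for k in (1, 2, 3, 4)]

    def sq(i: int, j: int) -> float:
        key = (i, j) if i < j else (j, i)
        return math.sqrt(Q[key])

    q = np.empty(4)
    for k in range(1, 5):
        others = [j for j in (1, 2, 3, 4) if j != k]
        cross = sum(sq(k, j) for j in others)
        corr = sum(sp[j - 1] for j in others)
        q[k - 1] = 0.5 * ((cross - corr) / 3.0 + sp[k - 1])
    clamped = bool((q < 0).any())
    q = np.clip(q, 0.0, None)
    freqs = GameteFreqs(q=q, locus_ids=classes.locus_ids)
    return freqs, {"clamped": clamped}


class BATGameteEstimator(BaseEstimator):
    """Scikit-learn style wrapper around the closed-form BAT estimator.

    ``fit(X)`` expects an (n_individuals, 3) integer array of codominant
    calls (0/1 parental homozygotes, 2 heterozygote, -1 missing); rows with
    a missing call are dropped.

    Attributes
    ----------
    q_ : ndarray (4,)
        Estimated sister-pair gamete frequencies q1..q4.
    class_freqs_ : CodominantClassFreqs
        Observed zygote-pair class frequencies.
    clamped_ : bool
        True if any negative raw estimate was clamped to zero.
    n_used_ : int
    """

    def fit(self, X, y=None):
        X = np.asarray(X)
        if X.ndim != 2 or X.shape[1] != 3:
            raise ValueError("X must be (n_individuals, 3) codominant calls")
        keep = (X != MISSING).all(axis=1)
        sub = X[keep]
        classes = CodominantClassFreqs(
            freqs=tally_zygote_calls(sub), n_used=int(sub.shape[0])
        )
        freqs, info = bat_estimate(classes)
        self.class_freqs_ = classes
        self.n_used_ = classes.n_used
        self.q_ = freqs.q
        self.clamped_ = info["clamped"]
        return self
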