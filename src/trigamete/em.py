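"""Two-point EM estimation of the recombination fraction in F2.

The standard comparison baseline: an F2 individual at a marker pair is the
union of two F1 gametes, each parental with probability (1-r)/2 per type and
recombinant with probability r/2 per type.  Observed classes (9 genotype
classes for codominant pairs, 4 phenotype classes for dominant pairs) mix
several of the 16 ordered gamete-pair configurations; EM distributes each
class over its configurations (E-step) and sets r to the expected recombinant
gamete fraction (M-step), constrained to [0, 0.5].

Linkage phase enters as the assignment of the second locus's dominant (or
labelled) allele to a parental strand; with ``phase_mode='unknown'`` both
phase models are fitted and the higher-likelihood one is returned.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator

from .data_model import (
    DOMINANT,
    MISSING,
    DegenerateInputError,
    GenotypeMatrix,
)

__all__ = ["EMResult", "TwoPointEM", "em_two_point"]

_GAMETES = [(0, 0), (0, 1), (1, 0), (1, 1)]  # allele origins at the two loci
_REC = np.array([g[0] ^ g[1] for g in _GAMETES])  # recombinant indicator


@dataclass
class EMResult:
    r_hat: float
    phase: str
    loglik: float
    iterations: int
    converged: bool


def _model_classes(marker_type: str, orientation: tuple[int, int]):
    """Class index (16,) of each ordered gamete-pair configuration.

    ``orientation[l]`` says which allele origin carries the '1' label (the
    dominant allele, for dominant markers) at locus l; coupling = (0, 0),
    repulsion = (0, 1).
    """
    class_idx = np.empty(16, dtype=np.intp)
    pair_rec = np.empty(16)
    for i, (ga, gb) in enumerate(itertools.product(_GAMETES, _GAMETES)):
        labels = [
            (ga[l] ^ orientation[l], gb[l] ^ orientation[l]) for l in range(2)
        ]
        if marker_type == "codominant":
            codes = [la if la == lb else 2 for la, lb in labels]
            class_idx[i] = codes[0] * 3 + codes[1]
            n_classes = 9
        else:
            doms = [int(la == 1 or lb == 1) for la, lb in labels]
            class_idx[i] = doms[0] * 2 + doms[1]
            n_classes = 4
        pair_rec[i] = _REC[_GAMETES.index(ga)] + _REC[_GAMETES.index(gb)]
    return class_idx, pair_rec, n_classes


def _observed_counts(calls2: np.ndarray, marker_type: str, n_classes: int):
    if marker_type == "codominant":
        idx = calls2[:, 0].astype(np.intp) * 3 + calls2[:, 1]
    else:
        idx = (calls2[:, 0] == DOMINANT).astype(np.intp) * 2 + (
            calls2[:, 1] == DOMINANT
        )
    return np.bincount(idx, minlength=n_classes).astype(float)


def _em_fit(
    counts: np.ndarray,
    class_idx: np.ndarray,
    pair_rec: np.ndarray,
    n_classes: int,
    r0: float = 0.25,
    tol: float = 1e-8,
    max_iter: int = 1000,
) -> tuple[float, float, int, bool]:
    N = counts.sum()
    obs = counts > 0
    r = r0
    loglik_prev = -math.inf
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        fg = np.array([(1 - r) / 2, r / 2, r / 2, (1 - r) / 2])
        pairp = np.outer(fg, fg).ravel()
        classp = np.bincount(class_idx, weights=pairp, minlength=n_classes)
        recw = np.bincount(class_idx, weights=pairp * pair_rec, minlength=n_classes)
        loglik = float(np.sum(counts[obs] * np.log(classp[obs])))
        # EM guarantee: the constrained M-step never decreases the likelihood
        assert loglik >= loglik_prev - 1e-9, "EM log-likelihood decreased"
        loglik_prev = loglik
        with np.errstate(invalid="ignore", divide="ignore"):
            cond_rec = np.where(classp > 0, recw / np.maximum(classp, 1e-300), 0.0)
        r_new = float(np.sum(counts * cond_rec) / (2.0 * N))
        r_new = min(max(r_new, 1e-12), 0.5)
        if abs(r_new - r) < tol:
            r = r_new
            converged = True
            break
        r = r_new
    fg = np.array([(1 - r) / 2, r / 2, r / 2, (1 - r) / 2])
    pairp = np.outer(fg, fg).ravel()
    classp = np.bincount(class_idx, weights=pairp, minlength=n_classes)
    loglik = float(np.sum(counts[obs] * np.log(classp[obs])))
    return r, loglik, it, converged


class TwoPointEM(BaseEstimator):
    """Scikit-learn style two-point EM recombination-fraction estimator.

    ``fit(X)`` expects an (n_individuals, 2) integer call matrix for one
    marker pair (codes per ``marker_type``; -1 missing, dropped rowwise).

    Attributes
    ----------
    r_ : float in [0, 0.5]
    phase_ : 'coupling' or 'repulsion' (the fitted phase model)
    loglik_, n_iter_, converged_, n_used_
    """

    def __init__(
        self,
        marker_type: str = "codominant",
        phase_mode: str = "unknown",
        r0: float = 0.25,
        tol: float = 1e-8,
        max_iter: int = 1000,
    ):
        self.marker_type = marker_type
        self.phase_mode = phase_mode
        self.r0 = r0
        self.tol = tol
        self.max_iter = max_iter

    def fit(self, X, y=None):
        if self.marker_type not in ("dominant", "codominant"):
            raise ValueError(f"unknown marker_type: {self.marker_type!r}")
        if self.phase_mode not in ("coupling", "repulsion", "unknown"):
            raise ValueError(f"unknown phase_mode: {self.phase_mode!r}")
        X = np.asarray(X)
        if X.ndim != 2 or X.shape[1] != 2:
            raise ValueError("X must be (n_individuals, 2) calls")
        sub = X[(X != MISSING).all(axis=1)]
        if sub.shape[0] == 0:
            raise DegenerateInputError("no complete-case individuals at this pair")
        for col in range(2):
            if np.unique(sub[:, col]).size < 2:
                raise DegenerateInputError(f"marker {col} is monomorphic")

        phases = (
            ["coupling", "repulsion"]
            if self.phase_mode == "unknown"
            else [self.phase_mode]
        )
        best: EMResult | None = None
        for phase in phases:
            orientation = (0, 0) if phase == "coupling" else (0, 1)
            class_idx, pair_rec, n_classes = _model_classes(
                self.marker_type, orientation
            )
            counts = _observed_counts(sub, self.marker_type, n_classes)
            r, loglik, it, conv = _em_fit(
                counts, class_idx, pair_rec, n_classes,
                r0=self.r0, tol=self.tol, max_iter=self.max_iter,
            )
            res = EMResult(r, phase, loglik, it, conv)
            if best is None or res.loglik > best.loglik:
                best = res

        self.n_used_ = int(sub.shape[0])
        self.r_ = best.r_hat
        self.phase_ = best.phase
        self.loglik_ = best.loglik
        self.n_iter_ = best.iterations
        self.converged_ = best.converged
        return self


def em_two_point(
    matrix: GenotypeMatrix,
    pair: tuple[str, str],
    phase_mode: str = "unknown",
    **kwargs,
) -> EMResult:
    """Two-point EM on a named marker pair of a genotype matrix."""
    idx = [matrix.marker_index(p) for p in pair]
    est = TwoPointEM(
        marker_type=matrix.marker_type, phase_mode=phase_mode, **kwargs
    ).fit(matrix.calls[:, idx])
    return EMResult(est.r_, est.phase_, est.loglik_, est.n_iter_, est.converged_)
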