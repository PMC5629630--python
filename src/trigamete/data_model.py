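"""Core domain types for three-point gamete analysis in F2 populations.

An F2 individual is the union of two F1 gametes.  Over an ordered locus
triple, gametes fall into four *sister pairs* (a gamete and its allelic
complement), assumed equally frequent in an F2 population:

===== ==================== ====================
class dominant notation    codominant notation
===== ==================== ====================
1     ABC / abc            111 / 000
2     Abc / aBC            100 / 011
3     ABc / abC            110 / 001
4     AbC / aBc            101 / 010
===== ==================== ====================

``q1..q4`` denote the per-gamete frequencies of these pairs, constrained by
``2(q1+q2+q3+q4) = 1``.  Estimators in this package produce :class:`GameteFreqs`
from genotype matrices; downstream mapping works on the normalized form.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

# Genotype call codes.  Codominant: HOM_A / HOM_B are the two parental
# homozygotes, HET the heterozygote.  Dominant: RECESSIVE is the fully
# recessive class, DOMINANT the indistinguishable A_/het class.
MISSING = -1
HOM_A = 0
HOM_B = 1
HET = 2
RECESSIVE = 0
DOMINANT = 2

CODOMINANT_CODES = frozenset({HOM_A, HOM_B, HET, MISSING})
DOMINANT_CODES = frozenset({RECESSIVE, DOMINANT, MISSING})

#: representative gamete of each sister-pair class, as 0/1 alleles at the
#: ordered triple (class 1 = abc, 2 = Abc, 3 = abC, 4 = aBc); the other
#: member of the pair is the bitwise complement.
CLASS_PATTERNS = np.array(
    [[0, 0, 0], [1, 0, 0], [0, 0, 1], [0, 1, 0]], dtype=np.int8
)

#: names of the fourteen codominant zygote-pair classes, in tally order.
CODOMINANT_CLASS_NAMES = (
    "P1", "P2", "P3", "P4",
    "P12", "P13", "P14", "P23", "P24", "P34",
    "P1234", "P1324", "P1423", "P222",
)

#: dominant three-locus phenotype classes in tally order (Q1..Q8);
#: each entry is the dominant/recessive state at the ordered triple.
DOMINANT_PHENOTYPE_PATTERNS = (
    (0, 0, 0),  # Q1: aabbcc
    (0, 0, 1),  # Q2: aabbC_
    (0, 1, 0),  # Q3: aaB_cc
    (1, 0, 0),  # Q4: A_bbcc
    (1, 1, 0),  # Q5: A_B_cc
    (1, 0, 1),  # Q6: A_bbC_
    (0, 1, 1),  # Q7: aaB_C_
    (1, 1, 1),  # Q8: A_B_C_ (uninformative)
)


class GenotypeDataError(ValueError):
    """Structural or coding problem in a genotype matrix or file."""


class EmptyDataError(GenotypeDataError):
    """No complete-case individuals available for a tally."""


class DegenerateInputError(GenotypeDataError):
    """Input admits no meaningful estimate (e.g. all-zero frequencies)."""


@dataclass
class GenotypeMatrix:
    """F2 genotype calls, individuals x markers.

    ``calls`` is an integer array with codominant codes {0, 1, 2} or dominant
    codes {0, 2}; missing calls are -1.
    """

    calls: np.ndarray
    markers: list[str]
    marker_type: str  # 'dominant' or 'codominant'

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        self.markers = list(self.markers)

    @property
    def n_individuals(self) -> int:
        return self.calls.shape[0]

    @property
    def n_markers(self) -> int:
        return self.calls.shape[1]

    def marker_index(self, name: str) -> int:
        try:
            return self.markers.index(name)
        except ValueError:
            raise GenotypeDataError(f"unknown marker name: {name!r}") from None

    def missing_rates(self) -> dict[str, float]:
        """Per-marker fraction of missing calls."""
        miss = (self.calls == MISSING).mean(axis=0)
        return dict(zip(self.markers, miss.tolist()))

    def triple_calls(self, triple: tuple[str, str, str]) -> np.ndarray:
        """Complete-case calls (n_used x 3) for an ordered marker triple.

        Individuals missing any of the three calls are dropped.
        """
        idx = [self.marker_index(t) for t in triple]
        sub = self.calls[:, idx]
        keep = (sub != MISSING).all(axis=1)
        return sub[keep]


def validate_matrix(matrix: GenotypeMatrix) -> GenotypeMatrix:
    """Validate shape and codes; return the matrix unchanged if legal.

    Raises :class:`GenotypeDataError` naming the first offending cell.
    """
    if matrix.calls.ndim != 2:
        raise GenotypeDataError(
            f"calls must be 2-D (individuals x markers), got shape {matrix.calls.shape}"
        )
    if matrix.calls.shape[1] != len(matrix.markers):
        raise GenotypeDataError(
            f"{matrix.calls.shape[1]} call columns but {len(matrix.markers)} marker names"
        )
    if len(set(matrix.markers)) != len(matrix.markers):
        raise GenotypeDataError("marker names are not unique")
    if matrix.marker_type not in ("dominant", "codominant"):
        raise GenotypeDataError(f"unknown marker_type: {matrix.marker_type!r}")
    legal = CODOMINANT_CODES if matrix.marker_type == "codominant" else DOMINANT_CODES
    bad = ~np.isin(matrix.calls, list(legal))
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise GenotypeDataError(
            f"illegal code {int(matrix.calls[i, j])} at individual {int(i)}, "
            f"marker {matrix.markers[int(j)]!r}"
        )
    return matrix


@dataclass
class GameteFreqs:
    """Estimated sister-pair gamete frequencies q1..q4 for one triple."""

    q: np.ndarray  # shape (4,)
    locus_ids: tuple[str, str, str]

    def __post_init__(self) -> None:
        self.q = np.asarray(self.q, dtype=float)

    @property
    def q1(self) -> float:
        return float(self.q[0])

    @property
    def q2(self) -> float:
        return float(self.q[1])

    @property
    def q3(self) -> float:
        return float(self.q[2])

    @property
    def q4(self) -> float:
        return float(self.q[3])


@dataclass
class NormalizedGameteFreqs:
    """Gamete frequencies rescaled so p1+p2+p3+p4 = 0.5 exactly."""

    p: np.ndarray
    locus_ids: tuple[str, str, str]

    def __post_init__(self) -> None:
        self.p = np.asarray(self.p, dtype=float)


@dataclass
class DominantPhenotypeFreqs:
    """Observed frequencies of the eight dominant three-locus phenotypes.

    ``qhat[k]`` is the relative frequency of phenotype class k+1 in the
    Q1..Q8 ordering (Q8, the triple-dominant class, is tallied for the
    sum-to-one invariant but carries no information for estimation).
    """

    qhat: np.ndarray  # shape (8,)
    n_used: int
    locus_ids: tuple[str, str, str] = ("a", "b", "c")

    def __post_init__(self) -> None:
        self.qhat = np.asarray(self.qhat, dtype=float)


@dataclass
class CodominantClassFreqs:
    """Frequencies of the fourteen complementary zygote-pair classes.

    Ordered as :data:`CODOMINANT_CLASS_NAMES`; P222 (triple heterozygote)
    is tallied but unused by the estimator.
    """

    freqs: np.ndarray  # shape (14,)
    n_used: int
    locus_ids: tuple[str, str, str] = ("a", "b", "c")

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)

    def __getitem__(self, name: str) -> float:
        return float(self.freqs[CODOMINANT_CLASS_NAMES.index(name)])


@dataclass
class TripleResult:
    """Inferred order, phase and recombination fractions for one triple.

    ``parental_class`` / ``double_co_class`` index the sister-pair classes
    1..4.  ``ordered_loci`` is (outer, middle, outer) with the outers kept
    in input order.  Phase is 'coupling' when the parental pair is class 1
    (abc/ABC), else 'repulsion' (the middle-differing locus sits on the
    opposite parental strand); 'ambiguous' marks tied extrema.
    """

    locus_ids: tuple[str, str, str]
    ordered_loci: tuple[str, str, str] | None
    phase: str
    parental_class: int | None
    double_co_class: int | None
    r_outer1_mid: float | None = None
    r_mid_outer2: float | None = None
    r_outer1_outer2: float | None = None
    ambiguous: bool = False

    def pair_fractions(self) -> dict[frozenset, float]:
        """Map each unordered locus pair to its recombination fraction."""
        if self.ordered_loci is None:
            return {}
        o1, mid, o2 = self.ordered_loci
        return {
            frozenset((o1, mid)): self.r_outer1_mid,
            frozenset((mid, o2)): self.r_mid_outer2,
            frozenset((o1, o2)): self.r_outer1_outer2,
        }


@dataclass
class ThetaMatrix:
    """Pairwise recombination fractions averaged over reference loci.

    ``theta[i, j]`` is NaN where no reference locus was eligible.
    """

    markers: list[str]
    theta: np.ndarray
    n_refs: np.ndarray

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.theta, index=self.markers, columns=self.markers)
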