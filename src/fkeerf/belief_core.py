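"""Mass functions over a frame of discernment and the belief-function
quantities driving the evidential tree criterion.

The frame of discernment Theta is an ordered list of N mutually exclusive
class hypotheses; a mass function (basic belief assignment) puts nonnegative
weight on subsets of Theta, zero on the empty set, summing to 1. Subsets are
indexed by bitmask: bit j set <=> class j in the subset, so index 0 is the
empty set and index 2^N - 1 is Theta itself.

Quantities implemented: Dempster's orthogonal-sum combination, the mass
average, the Jousselme distance (via the Jaccard similarity matrix over
subsets), Martin's strict/light and Hoarau's fair inclusion degrees, the
conflict measure C = (1 - symmetric fair inclusion) * Jousselme distance,
and the pignistic probability transform.

The classifier shipped here only ever uses N = 2 but everything is written
frame-generically (dense vectors over 2^N subsets, guarded at N <= 16).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Hashable, Iterable, Sequence

import numpy as np

_MAX_CLASSES = 16
_SUM_TOL = 1e-9


class BeliefError(ValueError):
    pass


class TotalConflictError(BeliefError):
    """Dempster combination of fully contradictory evidence (K = 1)."""


@dataclass(frozen=True)
class Frame:
    """Ordered frame of discernment; subsets indexed by bitmask."""

    classes: tuple[Hashable, ...]

    def __post_init__(self) -> None:
        if len(self.classes) < 1:
            raise BeliefError("frame needs at least one class")
        if len(self.classes) > _MAX_CLASSES:
            raise BeliefError(f"frame limited to {_MAX_CLASSES} classes")
        if len(set(self.classes)) != len(self.classes):
            raise BeliefError("classes must be distinct")

    @property
    def n_classes(self) -> int:
        return len(self.classes)

    @property
    def n_subsets(self) -> int:
        return 1 << self.n_classes

    @property
    def full_index(self) -> int:
        return self.n_subsets - 1

    def singleton_index(self, label: Hashable) -> int:
        try:
            return 1 << self.classes.index(label)
        except ValueError:
            raise BeliefError(f"unknown label {label!r}") from None

    def subset_members(self, index: int) -> tuple[Hashable, ...]:
        return tuple(c for j, c in enumerate(self.classes) if index >> j & 1)


def binary_frame() -> Frame:
    """The shipped classifier's frame: (+1 positive, -1 negative)."""
    return Frame((1, -1))


@dataclass
class MassFunction:
    """Dense basic belief assignment over the 2^N subsets of a frame."""

    frame: Frame
    masses: np.ndarray

    def __post_init__(self) -> None:
        self.masses = np.asarray(self.masses, dtype=float)
        if self.masses.shape != (self.frame.n_subsets,):
            raise BeliefError(
                f"mass vector must have length {self.frame.n_subsets}"
            )
        if np.any(self.masses < -_SUM_TOL):
            raise BeliefError("negative mass")
        self.masses = np.clip(self.masses, 0.0, None)
        if self.masses[0] != 0.0:
            raise BeliefError("mass on the empty set must be 0")
        if abs(self.masses.sum() - 1.0) > _SUM_TOL:
            raise BeliefError(f"masses sum to {self.masses.sum()}, not 1")

    def focal_indices(self) -> np.ndarray:
        return np.nonzero(self.masses > 0)[0]

    def is_categorical(self) -> bool:
        """All mass on one singleton (a crisp label embedded as evidence)."""
        foc = self.focal_indices()
        return len(foc) == 1 and int(foc[0]).bit_count() == 1

    def to_dict(self) -> dict[str, float]:
        return {str(int(i)): float(self.masses[i]) for i in self.focal_indices()}

    @classmethod
    def from_dict(cls, frame: Frame, d: dict) -> "MassFunction":
        m = np.zeros(frame.n_subsets)
        for k, v in d.items():
            m[int(k)] = float(v)
        return cls(frame, m)


def categorical_mass(frame: Frame, label: Hashable) -> MassFunction:
    """All mass on the singleton {label}: how a crisp training label enters
    the evidential machinery."""
    m = np.zeros(frame.n_subsets)
    m[frame.singleton_index(label)] = 1.0
    return MassFunction(frame, m)


def vacuous_mass(frame: Frame) -> MassFunction:
    """Total ignorance: all mass on Theta."""
    m = np.zeros(frame.n_subsets)
    m[frame.full_index] = 1.0
    return MassFunction(frame, m)


def _check_shared_frame(ms: Sequence[MassFunction]) -> Frame:
    frame = ms[0].frame
    for m in ms[1:]:
        if m.frame != frame:
            raise BeliefError("mass functions must share one frame")
    return frame


def dempster_combine(ms: Sequence[MassFunction]) -> MassFunction:
    """Dempster's rule: iterated orthogonal sum, renormalized by 1 - K.

    For n > 2 inputs the iterated pairwise combination equals the n-way
    orthogonal sum (associativity), which tests verify against a brute-force
    product oracle.
    """
    if not ms:
        raise BeliefError("nothing to combine")
    frame = _check_shared_frame(ms)
    out = ms[0].masses.copy()
    for other in ms[1:]:
        nxt = np.zeros(frame.n_subsets)
        conflict_mass = 0.0
        for i in np.nonzero(out > 0)[0]:
            for j in other.focal_indices():
                p = out[i] * other.masses[j]
                inter = int(i) & int(j)
                if inter == 0:
                    conflict_mass += p
                else:
                    nxt[inter] += p
        if conflict_mass >= 1.0 - 1e-12:
            raise TotalConflictError("total conflict (K = 1), combination undefined")
        out = nxt / (1.0 - conflict_mass)
    return MassFunction(frame, out)


def average_masses(ms: Sequence[MassFunction]) -> MassFunction:
    """Arithmetic mean per subset — the stable pooling used for leaf masses."""
    if not ms:
        raise BeliefError("empty list")
    frame = _check_shared_frame(ms)
    return MassFunction(frame, np.mean([m.masses for m in ms], axis=0))


@dataclass
class JaccardMatrix:
    """Jaccard similarity |A n B| / |A u B| between all subset pairs.

    d(empty, empty) = 1 by convention (irrelevant in practice since the empty
    set never carries mass, but it keeps the matrix positive definite on the
    support actually used).
    """

    D: np.ndarray

    @classmethod
    def for_frame(cls, frame: Frame) -> "JaccardMatrix":
        n = frame.n_subsets
        D = np.empty((n, n))
        for i in range(n):
            for j in range(n):
                if i == 0 and j == 0:
                    D[i, j] = 1.0
                else:
                    inter = (i & j).bit_count()
                    union = (i | j).bit_count()
                    D[i, j] = inter / union if union else 1.0
        return cls(D)


def jaccard_matrix(frame: Frame) -> JaccardMatrix:
    return JaccardMatrix.for_frame(frame)


def jousselme_distance(
    m_a: MassFunction, m_b: MassFunction, D: JaccardMatrix | None = None
) -> float:
    """sqrt(1/2 (ma - mb)^T D (ma - mb)); a metric in [0, 1]."""
    frame = _check_shared_frame([m_a, m_b])
    if D is None:
        D = JaccardMatrix.for_frame(frame)
    diff = m_a.masses - m_b.masses
    q = 0.5 * diff @ D.D @ diff
    return float(np.sqrt(max(q, 0.0)))  # clamp tiny negative rounding


def _inc(a: int, b: int) -> float:
    return 1.0 if (a & b) == a else 0.0


def inclusion_degree(m_a: MassFunction, m_b: MassFunction, mode: str = "fair") -> float:
    """Degree to which m_a's focal elements are contained in m_b's.

    strict: mean of the containment indicator over all focal pairs.
    light:  mean over m_a's focals of the best match among m_b's focals.
    fair:   strict, but restricted to focal elements other than Theta
            ("ignorance is contained only in itself"). If either restricted
            focal set is empty (a vacuous mass), the degree is defined as 1:
            total ignorance is read as included in anything, which makes the
            conflict measure vanish against every opponent.
    """
    frame = _check_shared_frame([m_a, m_b])
    fa = [int(i) for i in m_a.focal_indices()]
    fb = [int(i) for i in m_b.focal_indices()]
    if mode == "strict":
        return float(np.mean([_inc(a, b) for a in fa for b in fb]))
    if mode == "light":
        return float(np.mean([max(_inc(a, b) for b in fb) for a in fa]))
    if mode == "fair":
        full = frame.full_index
        la = [a for a in fa if a != full]
        lb = [b for b in fb if b != full]
        if not la or not lb:
            return 1.0
        return float(np.mean([_inc(a, b) for a in la for b in lb]))
    raise BeliefError(f"unknown inclusion mode {mode!r}")


def conflict(
    m_a: MassFunction, m_b: MassFunction, D: JaccardMatrix | None = None
) -> float:
    """Conflict measure C = (1 - delta_N) * d_J, the tree-split impurity.

    delta_N is the symmetric fair inclusion max(delta_F(a,b), delta_F(b,a)).
    For crisp categorical masses C is exactly 0 (same label) or 1 (different).
    """
    delta_n = max(
        inclusion_degree(m_a, m_b, "fair"), inclusion_degree(m_b, m_a, "fair")
    )
    c = (1.0 - delta_n) * jousselme_distance(m_a, m_b, D)
    return float(min(max(c, 0.0), 1.0))


def pignistic(m: MassFunction) -> np.ndarray:
    """BetP(class) = sum over focal sets containing it of mass / set size."""
    out = np.zeros(m.frame.n_classes)
    for idx in m.focal_indices():
        size = int(idx).bit_count()
        share = m.masses[idx] / size
        for j in range(m.frame.n_classes):
            if idx >> j & 1:
                out[j] += share
    return out
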