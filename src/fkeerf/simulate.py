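"""Seeded synthetic inputs with the statistical structure each stage assumes.

Three generators, all pure functions of their arguments (seed included):

* ``gen_sequences`` — random centered-U windows with a planted positional
  trinucleotide bias in the positive class. This is the class-separating
  signal the position-specific trinucleotide propensity encoder is built to
  detect; one-hot and chemical-property encodings pick up the same positions
  more weakly, qualitatively mirroring the encoders' relative strength on
  real pseudouridine data.
* ``gen_clusters`` — isotropic Gaussian blobs for membership/center recovery.
* ``gen_masses`` — random valid mass functions for belief-space property tests.

The default benchmark fixture is L=21, 100+100 sequences, two motif
positions planted at strength p=0.85 — strong enough that cross-validated
accuracy has a comfortable margin, small enough that full CV runs in minutes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .belief_core import Frame, MassFunction
from .encoders import FeatureMatrix
from .sequence_data import LabeledDataset, RnaSequence

_BASES = np.array(list("ACGU"))


class SimulationError(ValueError):
    pass


@dataclass(frozen=True)
class MotifSpec:
    """Positional trinucleotide bias planted in positive sequences.

    ``positions`` are 1-based window starts; at each, positives carry the
    paired trinucleotide with probability ``strength`` (0.25 is the uniform
    baseline; below it the 'motif' would be anti-enriched).
    """

    positions: tuple[int, ...]
    trinucleotides: tuple[str, ...]
    strength: float

    def __post_init__(self) -> None:
        if len(self.positions) != len(self.trinucleotides):
            raise SimulationError("positions and trinucleotides must pair up")
        if not 0.25 <= self.strength <= 1.0:
            raise SimulationError("strength must lie in [0.25, 1]")
        for t in self.trinucleotides:
            if len(t) != 3 or set(t) - set("ACGU"):
                raise SimulationError(f"bad trinucleotide {t!r}")

    def check_center_safe(self, L: int) -> None:
        center = (L + 1) // 2  # 1-based
        for p, t in zip(self.positions, self.trinucleotides):
            if not 1 <= p <= L - 2:
                raise SimulationError(f"motif start {p} outside 1..{L - 2}")
            if p <= center <= p + 2 and t[center - p] != "U":
                raise SimulationError(
                    f"motif at {p} would overwrite the central U with {t[center - p]!r}"
                )


def default_motif() -> MotifSpec:
    """Two planted trinucleotides flanking the central U of a 21-mer."""
    return MotifSpec(positions=(4, 14), trinucleotides=("GAC", "CGA"), strength=0.85)


def gen_sequences(
    n_pos: int,
    n_neg: int,
    L: int,
    motif: MotifSpec,
    seed: int = 0,
) -> LabeledDataset:
    """Uniform centered-U windows; positives additionally draw the motif
    trinucleotides at the motif positions with probability ``strength``."""
    if L < 3 or L % 2 == 0:
        raise SimulationError("L must be odd and >= 3")
    if n_pos < 1 or n_neg < 1:
        raise SimulationError("need at least one sequence per class")
    motif.check_center_safe(L)
    rng = np.random.default_rng(seed)
    center = L // 2  # 0-based
    ids, seqs, labels = [], [], []
    for label, count, prefix in ((1, n_pos, "pos"), (-1, n_neg, "neg")):
        for i in range(count):
            chars = _BASES[rng.integers(0, 4, size=L)].tolist()
            chars[center] = "U"
            if label == 1:
                for p, t in zip(motif.positions, motif.trinucleotides):
                    if rng.random() < motif.strength:
                        chars[p - 1 : p + 2] = list(t)
            chars[center] = "U"  # planting never overwrites the center (validated)
            ids.append(f"{prefix}_{i + 1}")
            seqs.append(RnaSequence("".join(chars)))
            labels.append(label)
    return LabeledDataset(ids, seqs, np.array(labels), species_tag="synthetic")


def default_fixture(seed: int = 1) -> LabeledDataset:
    """The shipped synthetic benchmark: 100+100 21-mers, p=0.85."""
    return gen_sequences(100, 100, 21, default_motif(), seed=seed)


def gen_clusters(
    m: int,
    n: int,
    K: int,
    separation: float,
    seed: int = 0,
) -> tuple[FeatureMatrix, np.ndarray]:
    """K isotropic unit-variance Gaussian blobs, centers ``separation``
    (in within-cluster sd units) apart along distinct axes. Returns the
    matrix and the true assignments."""
    if K > m:
        raise SimulationError("K must be <= m")
    if K > n:
        raise SimulationError("need n >= K for axis-aligned centers")
    rng = np.random.default_rng(seed)
    assign = np.sort(rng.integers(0, K, size=m)) if K > 1 else np.zeros(m, dtype=int)
    # guarantee every cluster occupied
    assign[:K] = np.arange(K)
    centers = np.zeros((K, n))
    for k in range(K):
        centers[k, k] = separation
    X = centers[assign] + rng.normal(0.0, 1.0, size=(m, n))
    names = [f"f{j}" for j in range(n)]
    return FeatureMatrix(X, names), assign


def gen_masses(
    frame: Frame,
    count: int,
    seed: int = 0,
    concentration: float = 1.0,
) -> list[MassFunction]:
    """Random valid mass functions: Dirichlet weights over the nonempty
    subsets with symmetric parameter 1/concentration, so large
    ``concentration`` concentrates mass on a single random subset
    (near-categorical limit) and 1.0 gives uniform Dirichlet draws."""
    if count < 1:
        raise SimulationError("count must be >= 1")
    if concentration <= 0:
        raise SimulationError("concentration must be > 0")
    rng = np.random.default_rng(seed)
    n_nonempty = frame.n_subsets - 1
    alpha = np.full(n_nonempty, 1.0 / concentration)
    out = []
    for _ in range(count):
        w = rng.dirichlet(alpha)
        if not np.isfinite(w).all() or w.sum() <= 0:  # extreme-alpha underflow
            w = np.zeros(n_nonempty)
            w[rng.integers(0, n_nonempty)] = 1.0
        masses = np.concatenate([[0.0], w / w.sum()])
        out.append(MassFunction(frame, masses))
    return out
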