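"""Sequence feature encodings: Binary (one-hot), NCP, PSTNPss and PseKNC.

Four per-sequence encodings and their concatenation into a sample x feature
matrix:

* **Binary** — one-hot over {A,C,G,U} per position, 4L features.
* **NCP** — three chemical-property bits per position (ring structure,
  functional group, hydrogen-bond strength), 3L features.
* **PSTNPss** — position-specific trinucleotide propensity, single strand:
  for every trinucleotide s and window start t, the difference between its
  relative frequency in the positive and in the negative training set,
  z[s,t] = F+(s|t) - F-(s|t). A sequence maps to the L-2 propensities of its
  own trinucleotides. This encoder is *fitted on training data only* and the
  fit must be repeated inside every CV fold: fitting on the full dataset
  leaks the test labels.
* **PseKNC** — pseudo k-tuple nucleotide composition: normalized k-mer
  frequencies plus lambda long-range correlation terms built from
  standardized dinucleotide physicochemical indices. The whole vector sums
  to 1 by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources as _ilres
from itertools import product
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .sequence_data import LabeledDataset, RnaSequence, POSITIVE, NEGATIVE

BASES = "ACGU"
#: 64 trinucleotides in lexicographic A<C<G<U order: AAA, AAC, ..., UUU
TRINUCLEOTIDES = ["".join(p) for p in product(BASES, repeat=3)]
TRINUC_INDEX = {t: i for i, t in enumerate(TRINUCLEOTIDES)}
DINUCLEOTIDES = ["".join(p) for p in product(BASES, repeat=2)]

_BINARY = {"A": (1, 0, 0, 0), "C": (0, 1, 0, 0), "G": (0, 0, 1, 0), "U": (0, 0, 0, 1)}
# (ring structure: purine=1, functional group: amino=1, hydrogen bond: weak=1)
_NCP = {"A": (1, 1, 1), "C": (0, 1, 0), "G": (1, 0, 0), "U": (0, 0, 1)}

ENCODER_NAMES = ("binary", "ncp", "pstnpss", "pseknc")


class EncoderError(ValueError):
    pass


@dataclass
class FeatureMatrix:
    """m samples x n features with provenance-carrying column names."""

    values: np.ndarray
    feature_names: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise EncoderError("feature matrix must be 2-D")
        if self.values.shape[1] != len(self.feature_names):
            raise EncoderError("feature_names do not match column count")
        if not np.all(np.isfinite(self.values)):
            raise EncoderError("feature matrix contains NaN/Inf")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, columns=self.feature_names)


def encode_binary(seq: RnaSequence) -> np.ndarray:
    """One-hot encoding, concatenated 5'->3'; length 4L, row-sum L."""
    return np.array([v for b in str(seq) for v in _BINARY[b]], dtype=float)


def encode_ncp(seq: RnaSequence) -> np.ndarray:
    """Nucleotide chemical property triples, concatenated; length 3L."""
    return np.array([v for b in str(seq) for v in _NCP[b]], dtype=float)


@dataclass
class PSTNPssModel:
    """Fitted 64 x (L-2) propensity matrix Z = F+ - F-, entries in [-1, 1]."""

    Z: np.ndarray
    L: int

    def __post_init__(self) -> None:
        self.Z = np.asarray(self.Z, dtype=float)
        if self.Z.shape != (64, self.L - 2):
            raise EncoderError(f"Z must be 64 x {self.L - 2}")
        if np.any(np.abs(self.Z) > 1 + 1e-12):
            raise EncoderError("propensities must lie in [-1, 1]")


def fit_pstnpss(train: LabeledDataset) -> PSTNPssModel:
    """Per-position trinucleotide frequency difference between classes.

    Frequencies are relative (count at position t divided by class size), so
    every entry of Z lies in [-1, 1].
    """
    train.require_both_classes()
    L = train.length
    counts = {POSITIVE: np.zeros((64, L - 2)), NEGATIVE: np.zeros((64, L - 2))}
    for seq, y in zip(train.sequences, train.labels):
        s = str(seq)
        c = counts[int(y)]
        for t in range(L - 2):
            c[TRINUC_INDEX[s[t : t + 3]], t] += 1.0
    z = counts[POSITIVE] / train.n_positive - counts[NEGATIVE] / train.n_negative
    return PSTNPssModel(Z=z, L=L)


def encode_pstnpss(model: PSTNPssModel, seq: RnaSequence) -> np.ndarray:
    """Look up the fitted propensity of each of the sequence's L-2 trinucleotides."""
    if len(seq) != model.L:
        raise EncoderError(f"sequence length {len(seq)} != model length {model.L}")
    s = str(seq)
    return np.array(
        [model.Z[TRINUC_INDEX[s[t : t + 3]], t] for t in range(model.L - 2)],
        dtype=float,
    )


def _load_default_index_table() -> dict[str, np.ndarray]:
    path = _ilres.files("fkeerf") / "resources" / "rna_dinuc_indices.csv"
    with _ilres.as_file(path) as p:
        df = pd.read_csv(p)
    df = df.set_index("dinucleotide")
    return {d: df.loc[d].to_numpy(dtype=float) for d in df.index}


def _standardize_index_table(table: Mapping[str, Sequence[float]]) -> dict[str, np.ndarray]:
    missing = set(DINUCLEOTIDES) - set(table)
    if missing:
        raise EncoderError(f"index table missing dinucleotides {sorted(missing)}")
    mat = np.array([np.asarray(table[d], dtype=float) for d in DINUCLEOTIDES])
    mu = mat.mean(axis=0)
    sd = mat.std(axis=0)
    sd[sd == 0] = 1.0
    mat = (mat - mu) / sd
    return {d: mat[i] for i, d in enumerate(DINUCLEOTIDES)}


@dataclass
class PseKNCConfig:
    """Parameters of the PseKNC encoding.

    k: tuple size (first block has 4^k components); lam: number of
    correlation tiers (lambda); omega: weight of the correlation block;
    index_table: dinucleotide -> sigma physicochemical index values,
    standardized to mean 0 / variance 1 across the 16 dinucleotides.
    """

    k: int = 2
    lam: int = 2
    omega: float = 0.1
    index_table: dict[str, np.ndarray] = field(default_factory=_load_default_index_table)

    def __post_init__(self) -> None:
        if self.k < 1:
            raise EncoderError("k must be >= 1")
        if self.lam < 0:
            raise EncoderError("lambda must be >= 0")
        if self.omega < 0:
            raise EncoderError("omega must be >= 0")
        self.index_table = _standardize_index_table(self.index_table)

    @property
    def n_features(self) -> int:
        return 4**self.k + self.lam

    def sigma(self) -> int:
        return len(next(iter(self.index_table.values())))


def _correlation(cfg: PseKNCConfig, d1: str, d2: str) -> float:
    """Mean squared index difference between two dinucleotides."""
    p1, p2 = cfg.index_table[d1], cfg.index_table[d2]
    return float(np.mean((p1 - p2) ** 2))


def encode_pseknc(seq: RnaSequence, cfg: PseKNCConfig) -> np.ndarray:
    """Normalized k-tuple frequencies plus lambda weighted correlation terms.

    The shared denominator (sum of k-mer frequencies + omega * sum of theta)
    makes the full 4^k + lambda vector sum to exactly 1.
    """
    s = str(seq)
    L = len(s)
    if cfg.lam >= L - 1:
        raise EncoderError(f"lambda={cfg.lam} must be < L-1={L - 1}")
    kmers = ["".join(p) for p in product(BASES, repeat=cfg.k)]
    kidx = {m: i for i, m in enumerate(kmers)}
    f = np.zeros(4**cfg.k)
    for t in range(L - cfg.k + 1):
        f[kidx[s[t : t + cfg.k]]] += 1.0
    f /= f.sum()  # relative frequencies of overlapping k-tuples
    theta = np.zeros(cfg.lam)
    for n in range(1, cfg.lam + 1):
        acc = 0.0
        for m in range(L - n - 1):
            acc += _correlation(cfg, s[m : m + 2], s[m + n : m + n + 2])
        theta[n - 1] = acc / (L - n - 1)
    denom = f.sum() + cfg.omega * theta.sum()
    return np.concatenate([f / denom, cfg.omega * theta / denom])


def encode_sequences(
    sequences: Sequence[RnaSequence],
    encoders: Sequence[str],
    pstnpss_model: PSTNPssModel | None = None,
    pseknc_cfg: PseKNCConfig | None = None,
) -> FeatureMatrix:
    """Encode sequences with the requested encoder blocks, in order.

    ``pstnpss_model`` must be supplied (pre-fitted on training data) when
    'pstnpss' is requested; ``pseknc_cfg`` defaults when 'pseknc' is.
    """
    if len(sequences) == 0:
        raise EncoderError("no sequences to encode")
    if not encoders:
        raise EncoderError("empty encoder list")
    unknown = set(encoders) - set(ENCODER_NAMES)
    if unknown:
        raise EncoderError(f"unknown encoders {sorted(unknown)}")
    if "pstnpss" in encoders and pstnpss_model is None:
        raise EncoderError("pstnpss requested but no fitted PSTNPssModel given")
    if "pseknc" in encoders and pseknc_cfg is None:
        pseknc_cfg = PseKNCConfig()

    L = len(sequences[0])
    blocks: list[np.ndarray] = []
    names: list[str] = []
    for enc in encoders:
        if enc == "binary":
            block = np.stack([encode_binary(s) for s in sequences])
            names += [f"binary:{i}" for i in range(4 * L)]
        elif enc == "ncp":
            block = np.stack([encode_ncp(s) for s in sequences])
            names += [f"ncp:{i}" for i in range(3 * L)]
        elif enc == "pstnpss":
            block = np.stack([encode_pstnpss(pstnpss_model, s) for s in sequences])
            names += [f"pstnpss:{i}" for i in range(L - 2)]
        else:  # pseknc
            block = np.stack([encode_pseknc(s, pseknc_cfg) for s in sequences])
            names += [f"pseknc:{i}" for i in range(pseknc_cfg.n_features)]
        blocks.append(block)
    return FeatureMatrix(np.hstack(blocks), names)


def encode_dataset(
    data: LabeledDataset,
    encoders: Sequence[str],
    pstnpss_model: PSTNPssModel | None = None,
    pseknc_cfg: PseKNCConfig | None = None,
) -> FeatureMatrix:
    """Encode a labeled dataset; rows align with its record order."""
    return encode_sequences(data.sequences, encoders, pstnpss_model, pseknc_cfg)


def build_feature_matrix(
    train: LabeledDataset,
    apply_to: LabeledDataset,
    encoders: Sequence[str],
    pseknc_cfg: PseKNCConfig | None = None,
) -> FeatureMatrix:
    """Fit the label-dependent PSTNPss block on ``train`` only, then encode
    ``apply_to``. Rows align with ``apply_to`` record order."""
    model = fit_pstnpss(train) if "pstnpss" in encoders else None
    return encode_dataset(apply_to, encoders, model, pseknc_cfg)
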