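"""Fuzzy-rule feature expansion: FCM-derived Gaussian antecedents that
enlarge an m x n feature matrix into an m x (1+n)K fuzzy feature set.

The pipeline fits fuzzy c-means on the (z-scored) training features; each of
the K clusters defines a rule with per-dimension center c_j^a and width
sigma_j^a = h * weighted variance (h is a manual scale). A sample's
normalized membership mu~^a in rule a is the softmax over rules of

    log mu^a = sum_j -(x_j - c_j^a)^2 / (2 sigma_j^a),

i.e. the product of per-dimension Gaussian memberships computed in log space
(the naive product underflows at n ~ 184; the two are mathematically
identical, which a small-n oracle test pins down). The expansion then
concatenates, rule by rule, mu~^a * (1, x): K affine copies of the sample
weighted by rule membership, plus the memberships themselves as the leading
entry of each block.

Only the rule antecedents are used; no TSK consequent is fitted — the forest
downstream does the discriminative work.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .encoders import FeatureMatrix

WIDTH_FLOOR = 1e-8


class FuzzyError(ValueError):
    pass


@dataclass
class Standardizer:
    """Per-feature z-score transform learned on training data."""

    mean: np.ndarray
    sd: np.ndarray  # floored so constant columns map to 0, not NaN

    @classmethod
    def fit(cls, X: np.ndarray) -> "Standardizer":
        sd = X.std(axis=0)
        sd = np.where(sd < WIDTH_FLOOR, 1.0, sd)
        return cls(mean=X.mean(axis=0), sd=sd)

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, dtype=float) - self.mean) / self.sd


def fit_fcm(
    X: np.ndarray,
    K_rules: int,
    fuzzifier: float = 2.0,
    tol: float = 1e-5,
    max_iter: int = 300,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Standard fuzzy c-means. Returns (centers K x n, memberships u m x K).

    Memberships follow the inverse-distance ratio with exponent 2/(f-1);
    centers are the u^f-weighted means. Initial centers are K distinct rows
    sampled with the given seed; iteration stops when the centers move less
    than ``tol`` (max absolute shift) or after ``max_iter`` rounds.
    """
    X = np.asarray(X, dtype=float)
    m, n = X.shape
    if K_rules < 1:
        raise FuzzyError("K_rules must be >= 1")
    if K_rules > m:
        raise FuzzyError(f"K_rules={K_rules} exceeds sample count {m}")
    if fuzzifier <= 1:
        raise FuzzyError("fuzzifier must be > 1")

    if K_rules == 1:
        return X.mean(axis=0, keepdims=True), np.ones((m, 1))

    uniq = np.unique(X, axis=0)
    if len(uniq) == 1:
        warnings.warn("all points identical; falling back to a single cluster")
        return X.mean(axis=0, keepdims=True), np.ones((m, 1))
    rng = np.random.default_rng(seed)
    # seed centers from distinct rows so no two initial centers coincide
    k_init = min(K_rules, len(uniq))
    centers = uniq[rng.choice(len(uniq), size=k_init, replace=False)]
    if k_init < K_rules:  # fewer distinct points than rules: duplicate + jitter
        extra = uniq[rng.choice(len(uniq), size=K_rules - k_init)]
        centers = np.vstack([centers, extra + rng.normal(0, 1e-6, extra.shape)])

    expo = 2.0 / (fuzzifier - 1.0)
    u = np.empty((m, K_rules))
    for _ in range(max_iter):
        d2 = ((X[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
        zero = d2 < 1e-300
        on_center = zero.any(axis=1)
        inv = np.where(zero, 1.0, d2) ** (-expo / 2.0)
        inv[on_center] = zero[on_center]  # points on a center: one-hot membership
        u = inv / inv.sum(axis=1, keepdims=True)
        uf = u**fuzzifier
        new_centers = (uf.T @ X) / uf.sum(axis=0)[:, None]
        shift = np.abs(new_centers - centers).max()
        centers = new_centers
        if shift < tol:
            break
    return centers, u


@dataclass
class FuzzyRuleBank:
    """FCM-derived rule antecedents plus the training standardizer."""

    centers: np.ndarray  # K x n, in standardized feature space
    widths: np.ndarray  # K x n, h-scaled weighted variances
    h: float
    standardizer: Standardizer
    membership: str = "gaussian"  # or "asymmetric_exp"

    def __post_init__(self) -> None:
        if self.centers.shape != self.widths.shape:
            raise FuzzyError("centers and widths must share shape")
        if not np.all(np.isfinite(self.centers)):
            raise FuzzyError("non-finite centers")
        if np.any(self.widths < WIDTH_FLOOR):
            raise FuzzyError("widths below floor")

    @property
    def K_rules(self) -> int:
        return self.centers.shape[0]

    @property
    def n_features(self) -> int:
        return self.centers.shape[1]


def fit_rule_bank(
    X: FeatureMatrix | np.ndarray,
    K_rules: int,
    h: float = 1.0,
    seed: int = 0,
    fuzzifier: float = 2.0,
    tol: float = 1e-5,
    max_iter: int = 300,
    weights: str = "plain",
    membership: str = "gaussian",
) -> FuzzyRuleBank:
    """Fit FCM on z-scored features and derive rule centers and widths.

    Centers are the u-weighted means and widths h times the u-weighted
    variances, with u the FCM memberships entering unpowered
    (``weights="plain"``; ``"powered"`` raises them to the fuzzifier as
    classical FCM would). Widths are floored at 1e-8 so constant columns
    stay finite.
    """
    raw = X.values if isinstance(X, FeatureMatrix) else np.asarray(X, dtype=float)
    std = Standardizer.fit(raw)
    Xs = std.transform(raw)
    _, u = fit_fcm(Xs, K_rules, fuzzifier, tol, max_iter, seed)
    if weights == "powered":
        u = u**fuzzifier
    elif weights != "plain":
        raise FuzzyError(f"unknown weights mode {weights!r}")
    wsum = u.sum(axis=0)  # > 0: memberships are row-normalized
    centers = (u.T @ Xs) / wsum[:, None]
    K_eff = centers.shape[0]
    widths = np.empty_like(centers)
    for a in range(K_eff):
        widths[a] = h * (u[:, a] @ (Xs - centers[a]) ** 2) / wsum[a]
    widths = np.maximum(widths, WIDTH_FLOOR)
    return FuzzyRuleBank(centers, widths, h, std, membership)


def _log_memberships(bank: FuzzyRuleBank, Xs: np.ndarray) -> np.ndarray:
    """Unnormalized log rule memberships, m x K, in standardized space."""
    diff = Xs[:, None, :] - bank.centers[None, :, :]
    if bank.membership == "asymmetric_exp":
        # non-squared, sign-dependent variant; kept for comparison only
        return (-diff / (2.0 * bank.widths[None, :, :])).sum(axis=2)
    return (-(diff**2) / (2.0 * bank.widths[None, :, :])).sum(axis=2)


def rule_memberships(bank: FuzzyRuleBank, x: np.ndarray) -> np.ndarray:
    """Normalized memberships mu~ of one raw sample; sums to 1.

    Computed as a stable softmax of the log memberships (subtract the max
    before exponentiating) — identical to normalizing the product of
    per-dimension Gaussians, without the underflow.
    """
    x = np.asarray(x, dtype=float)
    if x.shape != (bank.n_features,):
        raise FuzzyError(f"expected vector of length {bank.n_features}")
    logm = _log_memberships(bank, bank.standardizer.transform(x[None, :]))[0]
    logm -= logm.max()
    e = np.exp(logm)
    return e / e.sum()


@dataclass
class FuzzyFeatureSet:
    """The expanded matrix x_g: K blocks of mu~^a * (1, x) per sample."""

    values: np.ndarray
    rule_block_names: list[str]

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.values)):
            raise FuzzyError("fuzzy feature set contains NaN/Inf")


def fuzzy_transform(bank: FuzzyRuleBank, X: FeatureMatrix | np.ndarray) -> FuzzyFeatureSet:
    """Expand m x n features to m x (1+n)K; deterministic given the bank.

    Block a holds mu~^a * (1, x_standardized); the leading entries of the K
    blocks are the memberships themselves and sum to 1 across rules.
    """
    raw = X.values if isinstance(X, FeatureMatrix) else np.asarray(X, dtype=float)
    if raw.shape[1] != bank.n_features:
        raise FuzzyError(
            f"feature count {raw.shape[1]} does not match bank ({bank.n_features})"
        )
    Xs = bank.standardizer.transform(raw)
    logm = _log_memberships(bank, Xs)
    logm -= logm.max(axis=1, keepdims=True)
    mu = np.exp(logm)
    mu /= mu.sum(axis=1, keepdims=True)
    xe = np.hstack([np.ones((Xs.shape[0], 1)), Xs])  # (1, x)
    blocks = [mu[:, a : a + 1] * xe for a in range(bank.K_rules)]
    names = [
        f"rule{a + 1}:{part}"
        for a in range(bank.K_rules)
        for part in ["bias"] + [f"x{j}" for j in range(bank.n_features)]
    ]
    return FuzzyFeatureSet(np.hstack(blocks), names)
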