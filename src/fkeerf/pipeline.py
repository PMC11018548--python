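"""End-to-end model fitting, evaluation metrics, cross-validation, grid
search and JSON model serialization.

The full pipeline is: encode (binary + NCP + PSTNPss + PseKNC) -> fuzzy
feature expansion -> evidential forest -> co-leaf kernel prediction. Three
ablation variants are first-class:

* ``erf``    — evidential forest on the raw combined features, predicting by
               averaging leaf masses and maximizing pignistic probability.
* ``keerf``  — same features, prediction through the co-leaf kernel.
* ``fkeerf`` — kernel prediction on the fuzzy-expanded feature set (default).

Cross-validation is stratified and refits *everything* that touches labels
or feature statistics — the PSTNPss propensity table, the standardizer, the
fuzzy rule bank and the forest — on each fold's training portion only.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from itertools import product as _iterproduct
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import average_precision_score, roc_auc_score
from sklearn.model_selection import StratifiedKFold

from . import __version__ as _pkg_version
from .belief_core import binary_frame
from .encoders import (
    ENCODER_NAMES,
    FeatureMatrix,
    PSTNPssModel,
    PseKNCConfig,
    encode_dataset,
    encode_sequences,
    fit_pstnpss,
)
from .evidential_forest import (
    EvidentialForest,
    ForestParams,
    erf_predict_batch,
    fit_forest,
    forest_from_dict,
    forest_to_dict,
    predict_label_batch,
    predict_value_batch,
)
from .fuzzy_features import FuzzyRuleBank, Standardizer, fit_rule_bank, fuzzy_transform
from .sequence_data import DatasetError, LabeledDataset, RnaSequence

MODEL_FORMAT = "fkeerf-model"
MODEL_SCHEMA_VERSION = 1

VARIANTS = ("erf", "keerf", "fkeerf")


class PipelineError(ValueError):
    pass


class ModelIOError(ValueError):
    pass


@dataclass
class FitConfig:
    """Everything needed to train one model. The three hyperparameters the
    method tunes by grid search are K_rules (fuzzy clusters, grid 3..10),
    W (trees, grid 80..220 step 20) and min_leaf_samples (grid 3..10)."""

    encoders: tuple[str, ...] = ("binary", "pstnpss", "ncp", "pseknc")
    pseknc: PseKNCConfig = field(default_factory=PseKNCConfig)
    K_rules: int = 3
    h: float = 1.0
    fuzzifier: float = 2.0
    membership: str = "gaussian"
    fcm_weights: str = "plain"
    W: int = 100
    min_leaf_samples: int = 5
    max_depth: Optional[int] = None
    mtry: Optional[int] = None
    n_thresholds: int = 32
    seed: int = 0
    folds: int = 10
    variant: str = "fkeerf"
    pstnpss_scope: str = "fold"  # or "full": fit propensities once on all data

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise PipelineError(f"variant must be one of {VARIANTS}")
        unknown = set(self.encoders) - set(ENCODER_NAMES)
        if unknown:
            raise PipelineError(f"unknown encoders {sorted(unknown)}")
        if self.pstnpss_scope not in ("fold", "full"):
            raise PipelineError("pstnpss_scope must be 'fold' or 'full'")

    def forest_params(self) -> ForestParams:
        return ForestParams(
            W=self.W,
            min_leaf_samples=self.min_leaf_samples,
            max_depth=self.max_depth,
            mtry=self.mtry,
            n_thresholds=self.n_thresholds,
            seed=self.seed,
        )


@dataclass
class FkeerfModel:
    """A fitted model: encoder state + optional rule bank + forest."""

    config: FitConfig
    pstnpss: Optional[PSTNPssModel]
    rule_bank: Optional[FuzzyRuleBank]
    forest: EvidentialForest
    sequence_length: int
    version: int = MODEL_SCHEMA_VERSION


def fit_model(
    train: LabeledDataset,
    cfg: FitConfig,
    pstnpss_override: Optional[PSTNPssModel] = None,
) -> FkeerfModel:
    """Fit the full pipeline on ``train``.

    ``pstnpss_override`` injects a pre-fitted propensity table (used by the
    ``pstnpss_scope="full"`` cross-validation option); by default the table
    is fitted on ``train`` itself.
    """
    train.require_both_classes()
    pst = None
    if "pstnpss" in cfg.encoders:
        pst = pstnpss_override if pstnpss_override is not None else fit_pstnpss(train)
    X = encode_dataset(train, cfg.encoders, pst, cfg.pseknc)
    bank = None
    if cfg.variant == "fkeerf":
        bank = fit_rule_bank(
            X,
            cfg.K_rules,
            h=cfg.h,
            seed=cfg.seed,
            fuzzifier=cfg.fuzzifier,
            weights=cfg.fcm_weights,
            membership=cfg.membership,
        )
        features = fuzzy_transform(bank, X).values
    else:
        features = X.values
    forest = fit_forest(features, train.labels, cfg.forest_params())
    return FkeerfModel(
        config=cfg,
        pstnpss=pst,
        rule_bank=bank,
        forest=forest,
        sequence_length=train.length,
    )


def _model_features(model: FkeerfModel, seqs: Sequence[RnaSequence]) -> np.ndarray:
    for s in seqs:
        if len(s) != model.sequence_length:
            raise PipelineError(
                f"sequence length {len(s)} does not match model ({model.sequence_length})"
            )
    X = encode_sequences(seqs, model.config.encoders, model.pstnpss, model.config.pseknc)
    if model.rule_bank is not None:
        return fuzzy_transform(model.rule_bank, X).values
    return X.values


def predict_model(
    model: FkeerfModel, seqs: Sequence[RnaSequence]
) -> tuple[np.ndarray, np.ndarray]:
    """Predict (labels in {+1,-1}, continuous scores) for new sequences.

    Kernel variants score with F in [-1, 1] and label by sgn(F), sgn(0)=+1;
    the ``erf`` variant scores with BetP(positive) in [0, 1] and labels by
    maximal pignistic probability.
    """
    Xf = _model_features(model, seqs)
    if model.config.variant == "erf":
        return erf_predict_batch(model.forest, Xf)
    scores = predict_value_batch(model.forest, Xf)
    labels = np.where(scores >= 0, 1, -1)
    return labels, scores


@dataclass
class MetricsBundle:
    """Confusion counts and the derived scalar metrics."""

    TP: int
    FP: int
    TN: int
    FN: int
    SP: float
    SN: float
    ACC: float
    MCC: float
    Precision: float
    F1: float
    AUC: float
    AUPR: float

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _safe_div(num: float, den: float) -> float:
    return num / den if den != 0 else 0.0


def compute_metrics(
    y_true: Sequence[int], y_pred: Sequence[int], scores: Sequence[float]
) -> MetricsBundle:
    """Confusion-matrix metrics plus rank-based AUC/AUPR from the scores.

    MCC with a zero denominator is defined as 0; ratios with empty
    denominators (e.g. SP with no negatives) likewise.
    """
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    scores = np.asarray(scores, dtype=float)
    if not (len(y_true) == len(y_pred) == len(scores)):
        raise PipelineError("y_true, y_pred and scores must align")
    if len(y_true) == 0:
        raise PipelineError("empty input")
    tp = int(np.sum((y_true == 1) & (y_pred == 1)))
    fp = int(np.sum((y_true == -1) & (y_pred == 1)))
    tn = int(np.sum((y_true == -1) & (y_pred == -1)))
    fn = int(np.sum((y_true == 1) & (y_pred == -1)))
    sp = _safe_div(tn, tn + fp)
    sn = _safe_div(tp, fn + tp)
    acc = (tp + tn) / len(y_true)
    mcc_den = math.sqrt(
        float(tp + fp) * float(tp + fn) * float(tn + fn) * float(tn + fp)
    )
    mcc = _safe_div(tn * tp - fn * fp, mcc_den)
    precision = _safe_div(tp, tp + fp)
    f1 = _safe_div(2 * precision * sn, precision + sn)
    if len(np.unique(y_true)) == 2:
        auc = float(roc_auc_score(y_true, scores))
        aupr = float(average_precision_score(y_true, scores))
    else:  # degenerate single-class evaluation
        auc = float("nan")
        aupr = float("nan")
    return MetricsBundle(tp, fp, tn, fn, sp, sn, acc, mcc, precision, f1, auc, aupr)


def mean_metrics(bundles: Sequence[MetricsBundle]) -> MetricsBundle:
    """Counts summed, scalar metrics averaged across folds."""
    if not bundles:
        raise PipelineError("no metrics to average")
    return MetricsBundle(
        TP=sum(b.TP for b in bundles),
        FP=sum(b.FP for b in bundles),
        TN=sum(b.TN for b in bundles),
        FN=sum(b.FN for b in bundles),
        SP=float(np.mean([b.SP for b in bundles])),
        SN=float(np.mean([b.SN for b in bundles])),
        ACC=float(np.mean([b.ACC for b in bundles])),
        MCC=float(np.mean([b.MCC for b in bundles])),
        Precision=float(np.mean([b.Precision for b in bundles])),
        F1=float(np.mean([b.F1 for b in bundles])),
        AUC=float(np.mean([b.AUC for b in bundles])),
        AUPR=float(np.mean([b.AUPR for b in bundles])),
    )


def _fold_seed(seed: int, fold: int) -> int:
    return (seed * 1_000_003 + fold * 7919 + 1) % (2**31 - 1)


def cross_validate(
    data: LabeledDataset,
    cfg: FitConfig,
    folds: Optional[int] = None,
    seed: Optional[int] = None,
) -> tuple[MetricsBundle, list[MetricsBundle]]:
    """Stratified k-fold CV; every label-dependent stage refits per fold.

    With ``cfg.pstnpss_scope == "full"`` the propensity table alone is fitted
    once on the whole dataset (the optimistic, leaky protocol — available
    for comparison, not the default).
    """
    folds = cfg.folds if folds is None else folds
    seed = cfg.seed if seed is None else seed
    data.require_both_classes()
    if folds > min(data.n_positive, data.n_negative):
        raise PipelineError(
            f"{folds} folds exceed the smaller class ({min(data.n_positive, data.n_negative)})"
        )
    pst_full = None
    if cfg.pstnpss_scope == "full" and "pstnpss" in cfg.encoders:
        pst_full = fit_pstnpss(data)
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    per_fold: list[MetricsBundle] = []
    y = data.labels
    for fold, (tr, te) in enumerate(skf.split(np.zeros(len(data)), y)):
        fold_cfg = dataclasses.replace(cfg, seed=_fold_seed(seed, fold))
        model = fit_model(data.subset(tr), fold_cfg, pstnpss_override=pst_full)
        test = data.subset(te)
        pred, scores = predict_model(model, test.sequences)
        per_fold.append(compute_metrics(test.labels, pred, scores))
    return mean_metrics(per_fold), per_fold


def grid_search(
    data: LabeledDataset,
    grids: Optional[dict] = None,
    folds: Optional[int] = None,
    seed: int = 0,
    base_cfg: Optional[FitConfig] = None,
) -> tuple[FitConfig, pd.DataFrame]:
    """Exhaustive CV over {K_rules, W, min_leaf_samples} grids.

    Selection: highest mean ACC, ties broken by MCC, then by smaller W.
    Default grids are K_rules 3..10, W 80..220 step 20, min_leaf 3..10.
    """
    base = base_cfg if base_cfg is not None else FitConfig(seed=seed)
    grids = grids or {}
    k_grid = list(grids.get("K_rules", range(3, 11)))
    w_grid = list(grids.get("W", range(80, 221, 20)))
    leaf_grid = list(grids.get("min_leaf_samples", range(3, 11)))
    if not (k_grid and w_grid and leaf_grid):
        raise PipelineError("grids must be nonempty")
    rows = []
    best: Optional[tuple[tuple, FitConfig]] = None
    for k, w, leaf in _iterproduct(k_grid, w_grid, leaf_grid):
        cfg = dataclasses.replace(
            base, K_rules=k, W=w, min_leaf_samples=leaf, seed=seed
        )
        mean, _ = cross_validate(data, cfg, folds=folds, seed=seed)
        rows.append(
            {"K_rules": k, "W": w, "min_leaf_samples": leaf, **mean.to_dict()}
        )
        key = (-mean.ACC, -mean.MCC, w)
        if best is None or key < best[0]:
            best = (key, cfg)
    return best[1], pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# serialization

def _config_to_dict(cfg: FitConfig) -> dict:
    return {
        "encoders": list(cfg.encoders),
        "pseknc": {
            "k": cfg.pseknc.k,
            "lam": cfg.pseknc.lam,
            "omega": cfg.pseknc.omega,
            "index_table": {d: v.tolist() for d, v in cfg.pseknc.index_table.items()},
        },
        "K_rules": cfg.K_rules,
        "h": cfg.h,
        "fuzzifier": cfg.fuzzifier,
        "membership": cfg.membership,
        "fcm_weights": cfg.fcm_weights,
        "W": cfg.W,
        "min_leaf_samples": cfg.min_leaf_samples,
        "max_depth": cfg.max_depth,
        "mtry": cfg.mtry,
        "n_thresholds": cfg.n_thresholds,
        "seed": cfg.seed,
        "folds": cfg.folds,
        "variant": cfg.variant,
        "pstnpss_scope": cfg.pstnpss_scope,
    }


def _config_from_dict(d: dict) -> FitConfig:
    p = d["pseknc"]
    pseknc = PseKNCConfig(
        k=p["k"],
        lam=p["lam"],
        omega=p["omega"],
        index_table={k: np.asarray(v) for k, v in p["index_table"].items()},
    )
    return FitConfig(
        encoders=tuple(d["encoders"]),
        pseknc=pseknc,
        K_rules=d["K_rules"],
        h=d["h"],
        fuzzifier=d["fuzzifier"],
        membership=d["membership"],
        fcm_weights=d["fcm_weights"],
        W=d["W"],
        min_leaf_samples=d["min_leaf_samples"],
        max_depth=d["max_depth"],
        mtry=d["mtry"],
        n_thresholds=d["n_thresholds"],
        seed=d["seed"],
        folds=d["folds"],
        variant=d["variant"],
        pstnpss_scope=d["pstnpss_scope"],
    )


def model_to_dict(model: FkeerfModel) -> dict:
    bank = model.rule_bank
    return {
        "format": MODEL_FORMAT,
        "version": model.version,
        "package_version": _pkg_version,
        "sequence_length": model.sequence_length,
        "config": _config_to_dict(model.config),
        "pstnpss": (
            None
            if model.pstnpss is None
            else {"L": model.pstnpss.L, "Z": model.pstnpss.Z.tolist()}
        ),
        "rule_bank": (
            None
            if bank is None
            else {
                "centers": bank.centers.tolist(),
                "widths": bank.widths.tolist(),
                "h": bank.h,
                "mean": bank.standardizer.mean.tolist(),
                "sd": bank.standardizer.sd.tolist(),
                "membership": bank.membership,
            }
        ),
        "forest": forest_to_dict(model.forest),
    }


def model_from_dict(d: dict) -> FkeerfModel:
    if "version" not in d:
        raise ModelIOError("model file has no version field")
    if d.get("format") != MODEL_FORMAT or d["version"] != MODEL_SCHEMA_VERSION:
        raise ModelIOError(
            f"unsupported model format/version: {d.get('format')!r} v{d.get('version')!r}"
        )
    try:
        cfg = _config_from_dict(d["config"])
        pst = None
        if d["pstnpss"] is not None:
            pst = PSTNPssModel(Z=np.asarray(d["pstnpss"]["Z"]), L=d["pstnpss"]["L"])
        bank = None
        if d["rule_bank"] is not None:
            b = d["rule_bank"]
            bank = FuzzyRuleBank(
                centers=np.asarray(b["centers"]),
                widths=np.asarray(b["widths"]),
                h=b["h"],
                standardizer=Standardizer(np.asarray(b["mean"]), np.asarray(b["sd"])),
                membership=b["membership"],
            )
        forest = forest_from_dict(d["forest"])
        return FkeerfModel(
            config=cfg,
            pstnpss=pst,
            rule_bank=bank,
            forest=forest,
            sequence_length=d["sequence_length"],
            version=d["version"],
        )
    except (KeyError, TypeError) as exc:
        raise ModelIOError(f"malformed model file: {exc}") from exc


def save_model(model: FkeerfModel, path) -> None:
    """Write the model as JSON; identical fits serialize byte-identically."""
    with open(path, "w") as fh:
        json.dump(model_to_dict(model), fh, sort_keys=True, separators=(",", ":"))


def load_model(path) -> FkeerfModel:
    try:
        with open(path) as fh:
            d = json.load(fh)
    except json.JSONDecodeError as exc:
        raise ModelIOError(f"not valid JSON: {exc}") from exc
    return model_from_dict(d)
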