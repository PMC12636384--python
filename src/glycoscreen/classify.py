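"""Tiered classification models and repeated-split pooled ROC evaluation.

Model 1 uses the nine log-transformed tumor markers; Model 2 adds the two
sentinel glycopeptide levels; Model 3 additionally routes the full
glycopeptide feature block through a 100-component PCA fitted on training
rows only. Evaluation pools held-out predictions over repeated stratified
70/30 splits and computes the ROC by explicit threshold sweep.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.ensemble import HistGradientBoostingClassifier
from sklearn.model_selection import StratifiedShuffleSplit
from sklearn.neural_network import MLPClassifier

from .exceptions import ConfigurationError, InputDataError, UndefinedMetricError

logger = logging.getLogger(__name__)

MARKER_COLUMNS = (
    "CEA",
    "CA19-9",
    "CYFRA",
    "NCC-ST-439",
    "CA125",
    "PSA",
    "CA15-3",
    "AFP",
    "SCCA",
)


@dataclass
class ModelSpec:
    model_id: int = 3
    algorithm: str = "nn"  # "nn" or "gbt"
    n_components: int = 100
    train_fraction: float = 0.7
    n_repeats: int = 10
    seed: int = 0
    pca_on_all: bool = False  # optimistic variant: fit PCA on the full matrix

    def validate(self) -> None:
        if self.model_id not in (1, 2, 3):
            raise ConfigurationError("model_id must be 1, 2 or 3")
        if self.algorithm not in ("nn", "gbt"):
            raise ConfigurationError("algorithm must be 'nn' or 'gbt'")
        if not 0.0 < self.train_fraction < 1.0:
            raise ConfigurationError("train_fraction must be in (0, 1)")
        if self.n_repeats < 1 or self.n_components < 1:
            raise ConfigurationError("n_repeats and n_components must be >= 1")


@dataclass
class FeatureBlocks:
    """Column bookkeeping: which columns are routed through PCA."""

    direct_cols: List[str]
    pca_cols: List[str] = field(default_factory=list)


def log_transform_markers(marker_table: pd.DataFrame) -> pd.DataFrame:
    """log10(value + eps) per marker, eps = smallest positive observed value."""
    missing = [m for m in MARKER_COLUMNS if m not in marker_table.columns]
    if missing:
        raise InputDataError(f"missing marker column(s): {missing}")
    out = {}
    for m in MARKER_COLUMNS:
        v = marker_table[m].to_numpy(float)
        pos = v[v > 0]
        eps = pos.min() if len(pos) else 1.0
        out[f"log10_{m}"] = np.log10(v + eps)
    return pd.DataFrame(out, index=marker_table.index)


def assemble_features(
    model_id: int,
    marker_table: pd.DataFrame,
    glyco_levels: Optional[pd.DataFrame] = None,
    egp_matrix: Optional[pd.DataFrame] = None,
) -> Tuple[pd.DataFrame, FeatureBlocks]:
    """Build the samples-x-features table for one model tier.

    All inputs are indexed by sample id (rows = samples). Model 1: nine
    markers; Model 2: + two sentinel glycopeptides; Model 3: + glycopeptide
    block tagged for per-split PCA reduction.
    """
    if model_id not in (1, 2, 3):
        raise ConfigurationError("model_id must be 1, 2 or 3")
    X = log_transform_markers(marker_table)
    blocks = FeatureBlocks(direct_cols=list(X.columns))
    if model_id >= 2:
        if glyco_levels is None or glyco_levels.shape[1] != 2:
            raise InputDataError("model 2/3 needs a two-column sentinel glycopeptide table")
        g = glyco_levels.reindex(X.index).add_prefix("glyco__")
        if g.isna().any().any():
            raise InputDataError("sentinel glycopeptide levels missing for some samples")
        X = X.join(g)
        blocks.direct_cols += list(g.columns)
    if model_id == 3:
        if egp_matrix is None:
            raise InputDataError("model 3 needs the glycopeptide feature matrix")
        e = egp_matrix.reindex(X.index).add_prefix("egp__")
        if e.isna().any().any():
            raise InputDataError("glycopeptide matrix missing rows for some samples")
        X = X.join(e)
        blocks.pca_cols = list(e.columns)
    return X, blocks


@dataclass
class Standardizer:
    """Column-wise (x - mean) / sd with sd fitted on training rows only."""

    mean: np.ndarray
    scale: np.ndarray

    @classmethod
    def fit(cls, X: np.ndarray) -> "Standardizer":
        mean = X.mean(axis=0)
        scale = X.std(axis=0, ddof=0)
        scale[scale == 0] = 1.0
        return cls(mean=mean, scale=scale)

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (X - self.mean) / self.scale


def pca_reduce(
    train_block: np.ndarray,
    test_block: np.ndarray,
    n_components: int = 100,
) -> Tuple[np.ndarray, np.ndarray, Dict]:
    """Standardize + PCA fitted on the training block; project both blocks.

    If the block cannot support ``n_components`` the count is reduced with a
    warning; the actual count is recorded in the returned info dict.
    """
    if train_block.shape[0] < n_components + 1:
        logger.warning(
            "train rows (%d) < n_components + 1 (%d); reducing",
            train_block.shape[0], n_components + 1,
        )
    k = min(n_components, train_block.shape[0] - 1, train_block.shape[1])
    if k < 1:
        raise ConfigurationError("cannot fit any principal component")
    std = Standardizer.fit(train_block)
    pca = PCA(n_components=k, svd_solver="full")
    train_scores = pca.fit_transform(std.transform(train_block))
    if test_block.shape[0] == 0:
        test_scores = np.empty((0, pca.n_components_))
    else:
        test_scores = pca.transform(std.transform(test_block))
    info = {
        "n_components": int(pca.n_components_),
        "explained_variance": pca.explained_variance_.tolist(),
    }
    return train_scores, test_scores, info


def _make_classifier(algorithm: str, seed: int):
    if algorithm == "nn":
        return MLPClassifier(
            hidden_layer_sizes=(64, 32),
            activation="relu",
            early_stopping=True,
            max_iter=400,
            random_state=seed,
        )
    return HistGradientBoostingClassifier(random_state=seed)


@dataclass
class PooledPredictions:
    """Held-out predictions pooled over repeats."""

    frame: pd.DataFrame  # sample_id, repeat, y_true, p_hat
    splits: List[Dict[str, List[str]]]  # per repeat: train/test sample ids

    @property
    def n_pooled(self) -> int:
        return len(self.frame)


def repeated_split_eval(
    X: pd.DataFrame,
    y: Sequence[int],
    spec: ModelSpec,
    blocks: Optional[FeatureBlocks] = None,
) -> PooledPredictions:
    """Stratified repeated 70/30 evaluation with per-repeat preprocessing.

    Standardization and (for Model 3) PCA are fitted on the training rows of
    each repeat and applied to its held-out rows; no test information leaks
    into preprocessing unless ``spec.pca_on_all`` is set.
    """
    spec.validate()
    y = np.asarray(y, int)
    if len(np.unique(y)) < 2:
        raise InputDataError("both classes must be present")
    if blocks is None:
        blocks = FeatureBlocks(direct_cols=list(X.columns))
    direct = X[blocks.direct_cols].to_numpy(float)
    pca_block = X[blocks.pca_cols].to_numpy(float) if blocks.pca_cols else None

    global_pca_scores = None
    if pca_block is not None and spec.pca_on_all:
        s, _, _ = pca_reduce(pca_block, pca_block[:0], spec.n_components)
        global_pca_scores = s

    splitter = StratifiedShuffleSplit(
        n_splits=spec.n_repeats,
        train_size=spec.train_fraction,
        random_state=spec.seed,
    )
    sample_ids = np.asarray(X.index.astype(str))
    rows = []
    split_records = []
    for repeat, (tr, te) in enumerate(splitter.split(direct, y)):
        if len(np.unique(y[tr])) < 2:  # cannot happen with stratification; guard anyway
            logger.warning("single-class training split at repeat %d; reshuffled", repeat)
            continue
        std = Standardizer.fit(direct[tr])
        Xtr = std.transform(direct[tr])
        Xte = std.transform(direct[te])
        if pca_block is not None:
            if spec.pca_on_all:
                Xtr = np.hstack([Xtr, global_pca_scores[tr]])
                Xte = np.hstack([Xte, global_pca_scores[te]])
            else:
                str_, ste_, _ = pca_reduce(pca_block[tr], pca_block[te], spec.n_components)
                Xtr = np.hstack([Xtr, str_])
                Xte = np.hstack([Xte, ste_])
        clf = _make_classifier(spec.algorithm, spec.seed + repeat)
        clf.fit(Xtr, y[tr])
        p = clf.predict_proba(Xte)[:, 1]
        for i, idx in enumerate(te):
            rows.append((sample_ids[idx], repeat, int(y[idx]), float(p[i])))
        split_records.append(
            {"train": sample_ids[tr].tolist(), "test": sample_ids[te].tolist()}
        )
    frame = pd.DataFrame(rows, columns=["sample_id", "repeat", "y_true", "p_hat"])
    return PooledPredictions(frame=frame, splits=split_records)


@dataclass
class ROCResult:
    auc: float
    fpr: np.ndarray
    tpr: np.ndarray
    n_pooled: int


def roc_auc(scores: Sequence[float], labels: Sequence[int]) -> ROCResult:
    """Threshold-sweep ROC with trapezoidal AUC; ties step simultaneously."""
    s = np.asarray(scores, float)
    y = np.asarray(labels, int)
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise UndefinedMetricError("ROC undefined with a single class")
    order = np.argsort(-s, kind="stable")
    s_sorted = s[order]
    y_sorted = y[order]
    # collapse tied scores into simultaneous steps
    distinct = np.r_[np.diff(s_sorted) != 0, True]
    tp = np.cumsum(y_sorted == 1)[distinct]
    fp = np.cumsum(y_sorted == 0)[distinct]
    tpr = np.r_[0.0, tp / n_pos]
    fpr = np.r_[0.0, fp / n_neg]
    auc = float(np.trapezoid(tpr, fpr))
    return ROCResult(auc=auc, fpr=fpr, tpr=tpr, n_pooled=len(s))


def pooled_roc(pooled: PooledPredictions) -> ROCResult:
    return roc_auc(pooled.frame.p_hat.to_numpy(), pooled.frame.y_true.to_numpy())


def evaluate_model(
    model_id: int,
    marker_table: pd.DataFrame,
    labels: Sequence[int],
    spec: Optional[ModelSpec] = None,
    glyco_levels: Optional[pd.DataFrame] = None,
    egp_matrix: Optional[pd.DataFrame] = None,
) -> Tuple[PooledPredictions, ROCResult]:
    """Assemble a model tier, run repeated-split evaluation, pool the ROC."""
    spec = spec or ModelSpec(model_id=model_id)
    spec.model_id = model_id
    X, blocks = assemble_features(model_id, marker_table, glyco_levels, egp_matrix)
    pooled = repeated_split_eval(X, labels, spec, blocks)
    return pooled, pooled_roc(pooled)
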