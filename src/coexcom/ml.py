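"""Per-community case/control classification under repeated cross-validation.

For every community the scheme is: repeated stratified 5-fold CV; inside
each training split Boruta picks the community genes that beat their shadow
copies; a Random Forest (M = 300 trees, all S features considered at each
split) is trained on the confirmed genes and scored on the held-out fold
(accuracy, ROC AUC, F1 with "case" positive).  Per-repetition fold means are
aggregated to a mean and SD over repetitions.  Gene selection counts across
all fold x repetition Boruta runs give the selection frequencies, and the
top-N list takes the N most frequently selected genes, N being the average
confirmed count per fold.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import accuracy_score, f1_score, roc_auc_score
from sklearn.model_selection import StratifiedKFold

from coexcom.boruta import BorutaSelector
from coexcom.io import validate_metadata

logger = logging.getLogger(__name__)

POSITIVE_CLASS = "case"


@dataclasses.dataclass(frozen=True)
class CVConfig:
    n_folds: int = 5
    n_repetitions: int = 100
    base_seed: int = 0

    def __post_init__(self):
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")
        if self.n_repetitions < 1:
            raise ValueError("n_repetitions must be >= 1")


@dataclasses.dataclass(frozen=True)
class RFConfig:
    """Random-Forest settings: M trees; features per split s.

    ``features_per_split=None`` means s = S, every feature considered at
    every split; ``"sqrt"`` selects the conventional square-root rule.
    """
    n_trees: int = 300
    features_per_split: object = None

    def __post_init__(self):
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")


@dataclasses.dataclass
class CommunityPerformance:
    community_id: str
    n_genes: int
    accuracy_mean: float
    accuracy_sd: float
    auc_mean: float
    auc_sd: float
    f1_mean: float
    f1_sd: float
    boruta_avg_selected: float
    gene_frequency: dict
    gene_mean_importance: dict
    top_genes: list

    def to_row(self) -> dict:
        return {
            "community_id": self.community_id,
            "n_genes": self.n_genes,
            "accuracy_mean": self.accuracy_mean,
            "accuracy_sd": self.accuracy_sd,
            "auc_mean": self.auc_mean,
            "auc_sd": self.auc_sd,
            "f1_mean": self.f1_mean,
            "f1_sd": self.f1_sd,
            "boruta_avg_selected": self.boruta_avg_selected,
        }


def _fold_seed(base_seed: int, repetition: int, fold: int = 0) -> int:
    return (base_seed * 1000003 + repetition * 10007 + fold * 101) % (2 ** 31)


def stratified_folds(metadata: pd.DataFrame, config: CVConfig, repetition: int):
    """Stratified disjoint folds for one repetition; list of (train, test) id lists."""
    validate_metadata(metadata)
    y = metadata["class"].to_numpy()
    for cls in np.unique(y):
        if (y == cls).sum() < config.n_folds:
            raise ValueError(
                f"class {cls!r} has fewer members than n_folds={config.n_folds}")
    splitter = StratifiedKFold(n_splits=config.n_folds, shuffle=True,
                               random_state=_fold_seed(config.base_seed, repetition))
    ids = metadata.index.to_numpy()
    return [(ids[tr].tolist(), ids[te].tolist())
            for tr, te in splitter.split(np.zeros(len(ids)), y)]


def boruta_select(train_matrix: pd.DataFrame, train_labels, seed: int,
                  n_estimators: int = 30, max_iter: int = 20):
    """Boruta on one community's training split.

    ``train_matrix`` is genes x samples; returns (confirmed gene list,
    {gene: mean importance}).
    """
    X = train_matrix.to_numpy(dtype=float).T
    y = np.asarray(train_labels)
    selector = BorutaSelector(n_estimators=n_estimators, max_iter=max_iter,
                              random_state=seed)
    selector.fit(X, y)
    genes = list(train_matrix.index)
    confirmed = [g for g, keep in zip(genes, selector.support_) if keep]
    importances = {g: float(v) for g, v in zip(genes, selector.importances_mean_)}
    return confirmed, importances


def _make_rf(rf: RFConfig, seed: int) -> RandomForestClassifier:
    return RandomForestClassifier(
        n_estimators=rf.n_trees,
        max_features=rf.features_per_split,
        random_state=seed,
        n_jobs=1,
    )


def _score_fold(matrix, labels, train_ids, test_ids, genes, rf: RFConfig, seed: int):
    X_train = matrix.loc[genes, train_ids].to_numpy(dtype=float).T
    X_test = matrix.loc[genes, test_ids].to_numpy(dtype=float).T
    y_train = labels.loc[train_ids].to_numpy()
    y_test = labels.loc[test_ids].to_numpy()
    model = _make_rf(rf, seed)
    model.fit(X_train, y_train)
    pred = model.predict(X_test)
    case_col = list(model.classes_).index(POSITIVE_CLASS)
    proba = model.predict_proba(X_test)[:, case_col]
    return (
        accuracy_score(y_test, pred),
        roc_auc_score(y_test == POSITIVE_CLASS, proba),
        f1_score(y_test, pred, pos_label=POSITIVE_CLASS),
    )


def _run_cv(matrix: pd.DataFrame, metadata: pd.DataFrame, genes: list,
            community_id: str, cv: CVConfig, rf: RFConfig,
            boruta_trees: int = 30, boruta_max_iter: int = 20) -> CommunityPerformance:
    labels = metadata.loc[matrix.columns, "class"]
    sub = matrix.loc[genes]
    rep_metrics = np.zeros((cv.n_repetitions, 3))
    frequency = {g: 0 for g in genes}
    importance_sums = {g: 0.0 for g in genes}
    importance_counts = {g: 0 for g in genes}
    n_selected: list = []

    for rep in range(cv.n_repetitions):
        folds = stratified_folds(metadata.loc[matrix.columns], cv, rep)
        fold_metrics = np.zeros((len(folds), 3))
        for f, (train_ids, test_ids) in enumerate(folds):
            seed = _fold_seed(cv.base_seed, rep, f + 1)
            confirmed, importances = boruta_select(
                sub[train_ids], labels.loc[train_ids], seed,
                n_estimators=boruta_trees, max_iter=boruta_max_iter)
            n_selected.append(len(confirmed))
            for g in confirmed:
                frequency[g] += 1
            for g, v in importances.items():
                if np.isfinite(v):
                    importance_sums[g] += v
                    importance_counts[g] += 1
            # empty confirmation: fall back to the full community
            model_genes = confirmed if confirmed else genes
            fold_metrics[f] = _score_fold(sub, labels, train_ids, test_ids,
                                          model_genes, rf, seed)
        rep_metrics[rep] = fold_metrics.mean(axis=0)

    mean = rep_metrics.mean(axis=0)
    sd = rep_metrics.std(axis=0, ddof=1) if cv.n_repetitions > 1 else np.zeros(3)
    mean_importance = {
        g: (importance_sums[g] / importance_counts[g]) if importance_counts[g] else 0.0
        for g in genes
    }
    avg_selected = float(np.mean(n_selected))
    n_top = min(len(genes), int(round(avg_selected)))
    by_frequency = sorted(genes, key=lambda g: (-frequency[g], -mean_importance[g], g))
    top = sorted(by_frequency[:n_top], key=lambda g: (-mean_importance[g], g))
    return CommunityPerformance(
        community_id=community_id,
        n_genes=len(genes),
        accuracy_mean=float(mean[0]), accuracy_sd=float(sd[0]),
        auc_mean=float(mean[1]), auc_sd=float(sd[1]),
        f1_mean=float(mean[2]), f1_sd=float(sd[2]),
        boruta_avg_selected=avg_selected,
        gene_frequency=frequency,
        gene_mean_importance=mean_importance,
        top_genes=top,
    )


def evaluate_community(matrix: pd.DataFrame, metadata: pd.DataFrame, community,
                       cv: CVConfig = CVConfig(), rf: RFConfig = RFConfig(),
                       boruta_trees: int = 30,
                       boruta_max_iter: int = 20) -> CommunityPerformance:
    """Repeated-CV Boruta + Random-Forest evaluation of one community."""
    genes = list(community.genes)
    if not genes:
        raise ValueError("community has no genes")
    missing = [g for g in genes if g not in matrix.index]
    if missing:
        raise ValueError(f"community genes absent from matrix: {missing[:5]}")
    return _run_cv(matrix, metadata, genes, community.community_id, cv, rf,
                   boruta_trees, boruta_max_iter)


def validate_on_independent(matrix: pd.DataFrame, metadata: pd.DataFrame,
                            community, cv: CVConfig = CVConfig(),
                            rf: RFConfig = RFConfig(),
                            min_overlap: float = 0.5,
                            boruta_trees: int = 30,
                            boruta_max_iter: int = 20) -> CommunityPerformance:
    """Re-run the identical CV scheme on an independent dataset.

    Community genes absent from the independent matrix are dropped with a
    log entry; below ``min_overlap`` matched fraction the validation refuses.
    """
    genes = list(community.genes)
    matched = [g for g in genes if g in matrix.index]
    missing = sorted(set(genes) - set(matched))
    if missing:
        logger.warning("independent set lacks %d/%d genes of %s: %s",
                       len(missing), len(genes), community.community_id,
                       missing[:5])
    if len(genes) == 0 or len(matched) / len(genes) < min_overlap:
        raise ValueError(
            f"only {len(matched)}/{len(genes)} community genes present in the "
            f"independent matrix (need >= {min_overlap:.0%}); missing: {missing[:10]}")
    return _run_cv(matrix, metadata, matched, community.community_id, cv, rf,
                   boruta_trees, boruta_max_iter)


def screen_communities(performances, accuracy_threshold: float = 0.85):
    """Community ids with accuracy_mean above the threshold, best first.

    Ties in accuracy are resolved by community id so the output is stable.
    """
    performances = list(performances)
    if not performances:
        raise ValueError("no performances to screen")
    passed = [p for p in performances if p.accuracy_mean > accuracy_threshold]
    passed.sort(key=lambda p: (-p.accuracy_mean, p.community_id))
    return [p.community_id for p in passed]
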