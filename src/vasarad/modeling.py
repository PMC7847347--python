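"""Random-forest genotype models, model-order sweep, evaluation and fusion.

The class convention throughout: the predicted probability refers to the
*wildtype* class (label 1 internally).  Validation metrics are reported as
mean +/- sd over ``n_repeats`` repeated trainings with distinct seeds on the
same data, reflecting the stochastic variation of the forest itself.
Sensitivity/specificity/accuracy use a probability >= threshold decision
rule (default threshold 0.5) with wildtype as the positive class.

Decision-level fusion averages the predicted probabilities of the VASARI
model and the radiomics model with weight ``w`` on the VASARI side
(default 0.5, the unweighted mean).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from .types import LABELS, WILDTYPE, FeatureTable


@dataclass
class ModelConfig:
    """Random-forest hyperparameters and evaluation settings."""

    n_trees: int = 500
    max_depth: int | None = None
    min_samples_leaf: int = 1
    n_repeats: int = 10      # repeated trainings behind the "+/-" reporting
    threshold: float = 0.5   # operating point for sensitivity/specificity
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        if not 0.0 < self.threshold < 1.0:
            raise ValueError("threshold must be in (0, 1)")


@dataclass
class CohortSplit:
    train_ids: list
    validation_ids: list
    labels: dict

    def __post_init__(self) -> None:
        overlap = set(self.train_ids) & set(self.validation_ids)
        if overlap:
            raise ValueError(f"cohorts overlap: {sorted(overlap)[:3]} ...")


@dataclass
class TrainedModel:
    estimator: RandomForestClassifier
    features: list[str]
    bounds: dict[str, tuple[float, float]] | None
    config: ModelConfig
    seed: int


@dataclass
class RocCurve:
    auc: float
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray


@dataclass
class EvaluationReport:
    auc: float
    auc_sd: float
    sensitivity: float
    sensitivity_sd: float
    specificity: float
    specificity_sd: float
    accuracy: float
    accuracy_sd: float
    roc: RocCurve
    n_repeats: int

    def as_dict(self) -> dict:
        return {
            "auc": self.auc, "auc_sd": self.auc_sd,
            "sensitivity": self.sensitivity, "sensitivity_sd": self.sensitivity_sd,
            "specificity": self.specificity, "specificity_sd": self.specificity_sd,
            "accuracy": self.accuracy, "accuracy_sd": self.accuracy_sd,
            "n_repeats": self.n_repeats,
        }


@dataclass
class OrderSweepResult:
    orders: list[int]
    estimates: list          # Boot632Estimate per order
    optimal_order: int
    optimal_auc: float

    def features_at(self, selection_features: list[str], order: int) -> list[str]:
        return selection_features[:order]


def split_cohort(ids, labels: dict, train_fraction: float, seed: int = 0) -> CohortSplit:
    """Seeded label-stratified split into training and validation cohorts."""
    ids = list(ids)
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    train: list = []
    validation: list = []
    for cls in LABELS:
        members = [i for i in ids if labels[i] == cls]
        if len(members) < 2:
            raise ValueError(f"need >= 2 subjects of class {cls!r}")
        members = list(np.asarray(members, dtype=object)[rng.permutation(len(members))])
        n_train = int(round(train_fraction * len(members)))
        n_train = min(max(n_train, 1), len(members) - 1)
        train.extend(members[:n_train])
        validation.extend(members[n_train:])
    train.sort()
    validation.sort()
    return CohortSplit(train, validation, {i: labels[i] for i in ids})


def fit_forest(X: np.ndarray, y: np.ndarray, config: ModelConfig, seed: int):
    clf = RandomForestClassifier(
        n_estimators=config.n_trees,
        max_depth=config.max_depth,
        min_samples_leaf=config.min_samples_leaf,
        random_state=int(seed) % (2**31),
    )
    clf.fit(X, y)
    return clf


def predict_scores(clf, X: np.ndarray) -> np.ndarray:
    """Probability of the wildtype (positive, 1) class."""
    proba = clf.predict_proba(X)
    col = list(clf.classes_).index(1)
    return proba[:, col]


def train_model(
    table: FeatureTable, feature_subset: list[str], config: ModelConfig | None = None,
    seed: int | None = None,
) -> TrainedModel:
    """Fit a random forest on the given (already normalized) feature subset."""
    config = config or ModelConfig()
    seed = config.seed if seed is None else seed
    missing = [f for f in feature_subset if f not in table.feature_names]
    if missing:
        raise KeyError(f"unknown features: {missing}")
    y = table.label_array()
    if np.unique(y).size < 2:
        raise ValueError("both classes must be present in the training labels")
    X = table.data[list(feature_subset)].to_numpy()
    clf = fit_forest(X, y, config, seed)
    return TrainedModel(clf, list(feature_subset), table.bounds, config, seed)


def predict_probability(model: TrainedModel, table: FeatureTable) -> pd.Series:
    """Per-subject probability of wildtype under a trained model."""
    missing = [f for f in model.features if f not in table.feature_names]
    if missing:
        raise KeyError(f"table lacks model features: {missing}")
    scores = predict_scores(model.estimator, table.data[model.features].to_numpy())
    return pd.Series(scores, index=table.data.index, name="p_wildtype")


def roc_auc(scores, y) -> RocCurve:
    """AUC as the Mann-Whitney pair statistic (ties count 1/2) plus ROC points."""
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(y)
    if np.unique(y).size < 2:
        raise ValueError("both classes must be present to compute an AUC")
    from scipy.stats import rankdata

    pos = y == 1
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    ranks = rankdata(scores)
    auc = (ranks[pos].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)
    from sklearn.metrics import roc_curve

    fpr, tpr, thr = roc_curve(y, scores)
    return RocCurve(float(auc), fpr, tpr, thr)


def sweep_model_order(
    selection, table: FeatureTable, model_config: ModelConfig | None = None,
    n_replicates: int = 100, seed: int = 0,
) -> OrderSweepResult:
    """Train models on the top-k features for k = 1..len(selection).

    Each order is scored with the 0.632+ bootstrap AUC on the training
    table; the optimal order maximizes that AUC (ties go to the smaller,
    more parsimonious order).
    """
    from .selection import bootstrap_632plus_auc

    features = list(selection.features) if hasattr(selection, "features") else list(selection)
    if len(features) < 1:
        raise ValueError("selection must contain at least one feature")
    estimates = []
    for k in range(1, len(features) + 1):
        estimates.append(
            bootstrap_632plus_auc(
                table, features[:k], model_config, n_replicates=n_replicates, seed=seed
            )
        )
    aucs = [e.combined for e in estimates]
    optimal = int(np.argmax(aucs)) + 1  # argmax takes the first (smallest) maximum
    return OrderSweepResult(
        orders=list(range(1, len(features) + 1)),
        estimates=estimates,
        optimal_order=optimal,
        optimal_auc=float(aucs[optimal - 1]),
    )


def _metrics_at_threshold(scores: np.ndarray, y: np.ndarray, threshold: float):
    pred = scores >= threshold
    pos = y == 1
    tp = int((pred & pos).sum())
    fn = int((~pred & pos).sum())
    tn = int((~pred & ~pos).sum())
    fp = int((pred & ~pos).sum())
    sens = tp / (tp + fn) if tp + fn else np.nan
    spec = tn / (tn + fp) if tn + fp else np.nan
    acc = (tp + tn) / y.size
    return sens, spec, acc


def evaluate(
    train_table: FeatureTable,
    eval_table: FeatureTable,
    feature_subset: list[str],
    config: ModelConfig | None = None,
) -> EvaluationReport:
    """Evaluate repeated trainings of one feature subset on an evaluation cohort.

    The model is refit ``config.n_repeats`` times with distinct seeds on the
    training table and each fit is scored on the evaluation table; metrics
    are reported mean +/- sd across the repeats.  The ROC curve comes from
    the probabilities averaged over repeats.
    """
    config = config or ModelConfig()
    y = eval_table.label_array()
    aucs, senss, specs, accs = [], [], [], []
    mean_scores = np.zeros(y.size)
    for r in range(config.n_repeats):
        model = train_model(train_table, feature_subset, config, seed=config.seed + r)
        scores = predict_probability(model, eval_table).to_numpy()
        mean_scores += scores / config.n_repeats
        aucs.append(roc_auc(scores, y).auc)
        s, p, a = _metrics_at_threshold(scores, y, config.threshold)
        senss.append(s)
        specs.append(p)
        accs.append(a)
    roc = roc_auc(mean_scores, y)
    return EvaluationReport(
        auc=float(np.mean(aucs)), auc_sd=float(np.std(aucs)),
        sensitivity=float(np.mean(senss)), sensitivity_sd=float(np.std(senss)),
        specificity=float(np.mean(specs)), specificity_sd=float(np.std(specs)),
        accuracy=float(np.mean(accs)), accuracy_sd=float(np.std(accs)),
        roc=roc, n_repeats=config.n_repeats,
    )


def fuse_probabilities(p_vasari, p_radiomics, weight: float = 0.5):
    """Weighted average of two models' wildtype probabilities."""
    p_v = np.asarray(p_vasari, dtype=float)
    p_r = np.asarray(p_radiomics, dtype=float)
    if not 0.0 <= weight <= 1.0:
        raise ValueError("weight must be in [0, 1]")
    for name, p in (("p_vasari", p_v), ("p_radiomics", p_r)):
        if np.any((p < 0) | (p > 1)):
            raise ValueError(f"{name} contains values outside [0, 1]")
    fused = weight * p_v + (1.0 - weight) * p_r
    if isinstance(p_vasari, pd.Series):
        return pd.Series(fused, index=p_vasari.index, name="p_fused")
    return fused


def evaluate_fusion(
    train_vasari: FeatureTable,
    train_radiomics: FeatureTable,
    eval_vasari: FeatureTable,
    eval_radiomics: FeatureTable,
    vasari_features: list[str],
    radiomics_features: list[str],
    weight: float = 0.5,
    config: ModelConfig | None = None,
) -> EvaluationReport:
    """Repeated-training evaluation of the probability-fusion model."""
    config = config or ModelConfig()
    y = eval_vasari.label_array()
    if not np.array_equal(y, eval_radiomics.label_array()):
        raise ValueError("evaluation tables disagree on subjects or labels")
    aucs, senss, specs, accs = [], [], [], []
    mean_scores = np.zeros(y.size)
    for r in range(config.n_repeats):
        mv = train_model(train_vasari, vasari_features, config, seed=config.seed + r)
        mr = train_model(train_radiomics, radiomics_features, config,
                         seed=config.seed + 10_000 + r)
        fused = fuse_probabilities(
            predict_probability(mv, eval_vasari).to_numpy(),
            predict_probability(mr, eval_radiomics).to_numpy(),
            weight,
        )
        mean_scores += fused / config.n_repeats
        aucs.append(roc_auc(fused, y).auc)
        s, p, a = _metrics_at_threshold(fused, y, config.threshold)
        senss.append(s)
        specs.append(p)
        accs.append(a)
    roc = roc_auc(mean_scores, y)
    return EvaluationReport(
        auc=float(np.mean(aucs)), auc_sd=float(np.std(aucs)),
        sensitivity=float(np.mean(senss)), sensitivity_sd=float(np.std(senss)),
        specificity=float(np.mean(specs)), specificity_sd=float(np.std(specs)),
        accuracy=float(np.mean(accs)), accuracy_sd=float(np.std(accs)),
        roc=roc, n_repeats=config.n_repeats,
    )


def feature_correlation(
    vasari_table: FeatureTable, radiomics_table: FeatureTable
) -> pd.DataFrame:
    """Pearson r for every (VASARI feature, radiomics feature) pair.

    Constant columns have undefined correlation; their entries are recorded
    as 0 and the pair is flagged in the DataFrame attribute ``degenerate``.
    """
    if list(vasari_table.data.index) != list(radiomics_table.data.index):
        raise ValueError("tables must cover the same subjects in the same order")
    out = pd.DataFrame(
        0.0, index=vasari_table.feature_names, columns=radiomics_table.feature_names
    )
    degenerate = []
    for v in vasari_table.feature_names:
        x = vasari_table.data[v].to_numpy(dtype=float)
        for r in radiomics_table.feature_names:
            z = radiomics_table.data[r].to_numpy(dtype=float)
            if x.std() == 0 or z.std() == 0:
                degenerate.append((v, r))
                continue
            out.loc[v, r] = float(np.corrcoef(x, z)[0, 1])
    out.attrs["degenerate"] = degenerate
    return out


def augment_with_clinical(
    table: FeatureTable, age: pd.Series, gender: pd.Series
) -> FeatureTable:
    """Append age (years) and binary gender columns, scaled like other features."""
    ids = table.data.index
    for name, cov in (("age", age), ("gender", gender)):
        missing = ids.difference(cov.index)
        if len(missing):
            raise ValueError(f"missing {name} for subjects {list(missing)[:3]} ...")
    data = table.data.copy()
    age_v = age.loc[ids].astype(float)
    gender_v = (gender.loc[ids] == "male").astype(float)
    bounds = dict(table.bounds) if table.bounds is not None else None
    degenerate = set(table.degenerate)
    for name, col in (("age", age_v), ("gender", gender_v)):
        lo, hi = float(col.min()), float(col.max())
        if hi == lo:
            data[name] = 0.0
            degenerate.add(name)
        else:
            data[name] = (col - lo) / (hi - lo)
        if bounds is not None:
            bounds[name] = (lo, hi)
    return FeatureTable(data, table.labels.copy(), bounds=bounds,
                        degenerate=frozenset(degenerate))
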