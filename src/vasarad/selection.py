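"""Two-step feature selection: mRMR ranking, then 0.632+ bootstrap AUC.

Step 1 (candidate pool): greedy minimum-redundancy maximum-relevance (mRMR)
ranking in its difference form.  At each step the feature maximizing

    I(f; y) - (1/|S|) * sum_{s in S} I(f; s)

is appended to the selected set S, where I is the plug-in mutual information
(base-2) on discretized values.  Continuous features are discretized into 3
levels at mean +/- sd, the original mRMR convention.

Step 2 (ranking): each pooled feature is scored by the 0.632+ bootstrap AUC
of a single-feature classifier.  The estimator draws B bootstrap resamples,
trains on each and scores the out-of-bag subjects; the out-of-bag AUC is
blended with the apparent (resubstitution) AUC through the relative
overfitting rate

    R = (apparent - oob) / (apparent - 0.5),  clipped to [0, 1],
    w = 0.632 / (1 - 0.368 R),
    combined = (1 - w) * apparent + w * oob,

with 0.5 (chance-level AUC) playing the role of the no-information rate.
The top-k features by combined AUC form the selected set; ties break
lexicographically on the feature name.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .modeling import ModelConfig, fit_forest, predict_scores, roc_auc
from .types import FeatureTable


@dataclass
class MutualInformationEstimate:
    value: float          # bits
    scheme: str           # discretization applied to the inputs


@dataclass
class Boot632Estimate:
    apparent: float
    oob: float
    overfitting_rate: float
    weight: float
    combined: float
    per_replicate: list[float]
    n_replicates: int
    n_skipped: int

    @property
    def oob_mean(self) -> float:
        return float(np.mean(self.per_replicate))

    @property
    def oob_sd(self) -> float:
        return float(np.std(self.per_replicate))


@dataclass
class SelectionResult:
    features: list[str]
    aucs: list[float]
    pool: list[str]
    pool_size: int
    n_replicates: int
    seed: int
    estimates: dict[str, Boot632Estimate] = field(default_factory=dict)

    def top(self, k: int) -> list[str]:
        return self.features[:k]


def mutual_information(x, y) -> MutualInformationEstimate:
    """Plug-in mutual information (bits) from the joint contingency table."""
    x = np.asarray(x)
    y = np.asarray(y)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D sequences of equal length")
    if x.size < 2:
        raise ValueError("need at least 2 observations")
    _, xi = np.unique(x, return_inverse=True)
    _, yi = np.unique(y, return_inverse=True)
    joint = np.zeros((xi.max() + 1, yi.max() + 1))
    np.add.at(joint, (xi, yi), 1.0)
    p = joint / joint.sum()
    px = p.sum(axis=1, keepdims=True)
    py = p.sum(axis=0, keepdims=True)
    nz = p > 0
    value = float((p[nz] * np.log2(p[nz] / (px @ py)[nz])).sum())
    return MutualInformationEstimate(max(value, 0.0), "as-given")


def discretize_continuous(x: np.ndarray, max_discrete_levels: int = 10) -> np.ndarray:
    """Three-level mean +/- sd binning for continuous features.

    Columns with few distinct values (encoded categories) pass through
    unchanged; everything else maps to {0, 1, 2} for below mu - sigma,
    within, and above mu + sigma.
    """
    x = np.asarray(x, dtype=float)
    if np.unique(x).size <= max_discrete_levels:
        return x
    mu, sd = x.mean(), x.std()
    return np.digitize(x, [mu - sd, mu + sd]).astype(float)


def mrmr_rank(table: FeatureTable, pool_size: int | None = None) -> list[str]:
    """Greedy mRMR (difference form) ranking of the table's features."""
    names = sorted(table.feature_names)  # column-order invariance
    if len(names) < 1:
        raise ValueError("need at least one feature")
    y = table.label_array()
    if np.unique(y).size < 2:
        raise ValueError("both classes must be present for mRMR ranking")
    disc = {n: discretize_continuous(table.data[n].to_numpy()) for n in names}
    relevance = {n: mutual_information(disc[n], y).value for n in names}
    pair_cache: dict[tuple[str, str], float] = {}

    def pair_mi(a: str, b: str) -> float:
        key = (a, b) if a < b else (b, a)
        if key not in pair_cache:
            pair_cache[key] = mutual_information(disc[a], disc[b]).value
        return pair_cache[key]

    k = len(names) if pool_size is None else min(pool_size, len(names))
    selected: list[str] = []
    remaining = list(names)
    while len(selected) < k:
        if not selected:
            redundancy = {n: 0.0 for n in remaining}
        else:
            redundancy = {
                n: float(np.mean([pair_mi(n, s) for s in selected])) for n in remaining
            }
        scores = {n: relevance[n] - redundancy[n] for n in remaining}
        # higher score wins; tied scores prefer the less redundant feature,
        # then break lexicographically
        best = min(remaining, key=lambda n: (-scores[n], redundancy[n], n))
        selected.append(best)
        remaining.remove(best)
    return selected


def bootstrap_632plus_auc(
    table: FeatureTable,
    feature_subset: list[str],
    model_config: ModelConfig | None = None,
    n_replicates: int = 100,
    seed: int = 0,
) -> Boot632Estimate:
    """0.632+ bootstrap AUC of a classifier on the given feature subset."""
    if n_replicates < 2:
        raise ValueError("n_replicates must be >= 2")
    config = model_config or ModelConfig()
    X = table.data[list(feature_subset)].to_numpy()
    y = table.label_array()
    if np.unique(y).size < 2:
        raise ValueError("both classes must be present")
    n = y.size

    full = fit_forest(X, y, config, seed)
    apparent = roc_auc(predict_scores(full, X), y).auc

    rng = np.random.default_rng(seed)
    oob_aucs: list[float] = []
    skipped = 0
    for _ in range(n_replicates):
        idx = rng.integers(0, n, size=n)
        oob = np.setdiff1d(np.arange(n), idx)
        if (
            oob.size == 0
            or np.unique(y[oob]).size < 2
            or np.unique(y[idx]).size < 2
        ):
            skipped += 1
            continue
        model = fit_forest(X[idx], y[idx], config, seed=int(rng.integers(2**31)))
        oob_aucs.append(roc_auc(predict_scores(model, X[oob]), y[oob]).auc)
    if not oob_aucs:
        raise ValueError("every bootstrap replicate had a single-class out-of-bag set")
    oob_auc = float(np.mean(oob_aucs))

    if apparent <= 0.5:
        rate = 0.0
    else:
        rate = float(np.clip((apparent - oob_auc) / (apparent - 0.5), 0.0, 1.0))
    weight = 0.632 / (1.0 - 0.368 * rate)
    combined = (1.0 - weight) * apparent + weight * oob_auc
    return Boot632Estimate(
        apparent=float(apparent),
        oob=oob_auc,
        overfitting_rate=rate,
        weight=float(weight),
        combined=float(combined),
        per_replicate=oob_aucs,
        n_replicates=n_replicates,
        n_skipped=skipped,
    )


def combine_632plus(apparent: float, oob: float) -> tuple[float, float, float]:
    """Closed-form 0.632+ combination of an apparent and an out-of-bag AUC."""
    if apparent <= 0.5:
        rate = 0.0
    else:
        rate = float(np.clip((apparent - oob) / (apparent - 0.5), 0.0, 1.0))
    weight = 0.632 / (1.0 - 0.368 * rate)
    return rate, weight, (1.0 - weight) * apparent + weight * oob


def select_top_features(
    table: FeatureTable,
    k: int,
    pool_size: int | None = None,
    model_config: ModelConfig | None = None,
    n_replicates: int = 100,
    seed: int = 0,
) -> SelectionResult:
    """mRMR pool, then top-k features by single-feature 0.632+ bootstrap AUC."""
    n_features = len(table.feature_names)
    pool_size = n_features if pool_size is None else pool_size
    if not k <= pool_size <= n_features:
        raise ValueError("need k <= pool_size <= number of features")
    pool = mrmr_rank(table, pool_size)
    estimates = {
        name: bootstrap_632plus_auc(
            table, [name], model_config, n_replicates=n_replicates, seed=seed
        )
        for name in pool
    }
    ranked = sorted(pool, key=lambda n: (-estimates[n].combined, n))
    top = ranked[:k]
    return SelectionResult(
        features=top,
        aucs=[estimates[n].combined for n in top],
        pool=pool,
        pool_size=pool_size,
        n_replicates=n_replicates,
        seed=seed,
        estimates=estimates,
    )
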