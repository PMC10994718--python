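"""Perceptron edge classifier, metrics, and the sampler-bias experiment.

The experiment mirrors the three-phase link-prediction pipeline: features
(possibly embeddings) are built on the graph, a perceptron is trained on
positive edges plus sampled negatives (phase 2), and held-out positives plus
independently sampled negatives measure performance (phase 3). Crossing the
train-phase sampler with the evaluation-phase sampler (UNS x DANS) exposes
how much of the measured performance is an artifact of evaluating against
uniformly sampled — typically low-degree — negatives.

"Ten-fold cross validation with training size of 0.75" is realized as ten
Monte-Carlo repeated holdouts at a 75/25 split (standard k-fold would force a
0.9 train fraction). Within one replicate the positive split is shared across
all sampler conditions, giving a paired design.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import average_precision_score, roc_auc_score

from ._rng import derive_rng, derive_seed
from .features import EdgeFeatureMatrix, degree_pair, hadamard, topological_index
from .graph import Graph, remove_edges
from .sampling import sample_negative_edges

__all__ = [
    "ConfusionCounts",
    "CVResult",
    "PerceptronConfig",
    "PerceptronModel",
    "mcc",
    "binary_metrics",
    "train_perceptron",
    "monte_carlo_cv",
    "experiment_grid",
    "FeatureFunction",
    "degree_pair_feature",
    "topological_feature",
    "embedding_feature",
    "inflation_test",
    "plot_metric_bars",
]


# --------------------------------------------------------------------------
# metrics


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def mcc(c: ConfusionCounts) -> float:
    """Matthews correlation coefficient.

    (TP·TN − FP·FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN)); ranges from −1
    (perfect misclassification) to +1 (perfect classification), 0 at chance.
    Any zero factor in the denominator returns 0 by convention.
    """
    tp, tn, fp, fn = (float(x) for x in (c.tp, c.tn, c.fp, c.fn))
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        return 0.0
    return (tp * tn - fp * fn) / np.sqrt(denom)


def _confusion(scores: np.ndarray, labels: np.ndarray, threshold: float) -> ConfusionCounts:
    pred = scores >= threshold
    pos = labels == 1
    return ConfusionCounts(
        tp=int((pred & pos).sum()),
        tn=int((~pred & ~pos).sum()),
        fp=int((pred & ~pos).sum()),
        fn=int((~pred & pos).sum()),
    )


def binary_metrics(scores, labels, threshold: float = 0.5) -> dict:
    """MCC/F1 at a threshold plus threshold-free AUROC and AUPRC."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if len(np.unique(labels)) < 2:
        raise ValueError("labels must contain both classes")
    c = _confusion(scores, labels, threshold)
    precision = c.tp / (c.tp + c.fp) if (c.tp + c.fp) else 0.0
    recall = c.tp / (c.tp + c.fn) if (c.tp + c.fn) else 0.0
    f1 = 2 * precision * recall / (precision + recall) if (precision + recall) else 0.0
    return {
        "mcc": mcc(c),
        "auroc": float(roc_auc_score(labels, scores)),
        "auprc": float(average_precision_score(labels, scores)),
        "f1": float(f1),
    }


# --------------------------------------------------------------------------
# perceptron


@dataclass(frozen=True)
class PerceptronConfig:
    epochs: int = 100
    learning_rate: float = 0.01
    batch_size: int = 32


@dataclass(frozen=True)
class PerceptronModel:
    """Single linear layer with logistic output."""

    weights: np.ndarray
    bias: float
    mean: np.ndarray | None = None  # standardization fitted on the train split
    std: np.ndarray | None = None

    def predict_proba(self, X) -> np.ndarray:
        X = _as_matrix(X)
        if self.mean is not None:
            X = (X - self.mean) / self.std
        z = X @ self.weights + self.bias
        return 1.0 / (1.0 + np.exp(-np.clip(z, -500, 500)))


def _as_matrix(X) -> np.ndarray:
    if isinstance(X, EdgeFeatureMatrix):
        X = X.matrix
    return np.asarray(X, dtype=float)


def train_perceptron(
    features,
    labels,
    config: PerceptronConfig | None = None,
    seed: int = 0,
    standardize: bool = False,
) -> PerceptronModel:
    """Mini-batch gradient descent on binary cross-entropy."""
    config = config or PerceptronConfig()
    X = _as_matrix(features)
    y = np.asarray(labels, dtype=float)
    if not np.isfinite(X).all():
        raise ValueError("non-finite features")
    frac = y.mean()
    if not 0.3 <= frac <= 0.7:
        import warnings

        warnings.warn(f"label balance {frac:.2f} is far from 0.5", stacklevel=2)
    mean = std = None
    if standardize:
        mean = X.mean(axis=0)
        std = X.std(axis=0)
        std = np.where(std == 0, 1.0, std)
        X = (X - mean) / std
    rng = np.random.default_rng(seed)
    w = np.zeros(X.shape[1])
    b = 0.0
    n = len(y)
    for _ in range(config.epochs):
        perm = rng.permutation(n)
        for start in range(0, n, config.batch_size):
            idx = perm[start : start + config.batch_size]
            z = X[idx] @ w + b
            p = 1.0 / (1.0 + np.exp(-np.clip(z, -500, 500)))
            g = p - y[idx]
            w -= config.learning_rate * (X[idx].T @ g) / len(idx)
            b -= config.learning_rate * g.mean()
    return PerceptronModel(weights=w, bias=b, mean=mean, std=std)


# --------------------------------------------------------------------------
# feature functions


@dataclass
class FeatureFunction:
    """Named per-edge feature builder used by the CV driver.

    ``needs_training_graph`` marks features (embeddings) that must be built
    on the graph with the test positives removed; structural features use the
    full reference graph. ``standardize`` controls perceptron-side scaling.
    """

    fn: callable
    name: str
    needs_training_graph: bool = False
    standardize: bool = False

    def __call__(self, graph: Graph, pairs) -> np.ndarray:
        return _as_matrix(self.fn(graph, pairs))


def degree_pair_feature() -> FeatureFunction:
    return FeatureFunction(degree_pair, "degree_pair")


def topological_feature(scheme: str, exclude_self_edge: bool = False) -> FeatureFunction:
    return FeatureFunction(
        lambda g, pairs: topological_index(g, pairs, scheme, exclude_self_edge),
        scheme,
    )


def embedding_feature(method: str, config=None, seed: int = 0) -> FeatureFunction:
    """Hadamard of node embeddings trained on the (test-removed) graph.

    The trained embedding is cached per graph object, so within one replicate
    the four sampler conditions share a single training run.
    """
    from .embeddings import default_config, embed_graph

    cfg = config if config is not None else default_config(method)
    cache: dict = {}

    def fn(graph: Graph, pairs):
        key = id(graph)
        if key not in cache:
            cache.clear()  # keep at most one graph's embedding in memory
            cache[key] = embed_graph(graph, method, cfg, seed=seed)
        return hadamard(cache[key], pairs)

    return FeatureFunction(fn, f"{method}-hadamard", needs_training_graph=True, standardize=True)


# --------------------------------------------------------------------------
# cross-validation and the sampler grid

METRICS = ("mcc", "auroc", "auprc", "f1")


@dataclass(frozen=True)
class CVResult:
    """Per-replicate metric table plus mean ± std summary."""

    per_replicate: pd.DataFrame
    group_columns: tuple = ("feature", "train_sampler", "eval_sampler")

    def summary(self) -> pd.DataFrame:
        out = (
            self.per_replicate.groupby(list(self.group_columns))[list(METRICS)]
            .agg(["mean", "std"])
            .reset_index()
        )
        out.columns = [
            c[0] if not c[1] else f"{c[0]}_{c[1]}" for c in out.columns.to_flat_index()
        ]
        return out

    def to_long(self) -> pd.DataFrame:
        return self.per_replicate.melt(
            id_vars=["replicate", *self.group_columns],
            value_vars=list(METRICS),
            var_name="metric",
            value_name="value",
        )


def _split_positives(positives: np.ndarray, train_size: float, rng) -> tuple:
    m = len(positives)
    n_train = int(round(train_size * m))
    perm = rng.permutation(m)
    return positives[perm[:n_train]], positives[perm[n_train:]]


def _run_condition(
    g: Graph,
    train_graph: Graph,
    train_pos: np.ndarray,
    test_pos: np.ndarray,
    feature_fn: FeatureFunction,
    train_sampler: str,
    eval_sampler: str,
    replicate: int,
    seed: int,
    perceptron: PerceptronConfig | None,
    threshold: float,
) -> dict:
    n_train, n_test = len(train_pos), len(test_pos)
    train_neg = sample_negative_edges(
        g, train_sampler, n_train, derive_seed(seed, "neg", replicate, "train", train_sampler)
    ).edges
    eval_neg = sample_negative_edges(
        g, eval_sampler, n_test, derive_seed(seed, "neg", replicate, "eval", eval_sampler)
    ).edges
    # evaluation negatives must be disjoint from every positive (train or test)
    assert not g.has_edges(eval_neg).any(), "evaluation negative collides with a positive"
    feat_graph = train_graph if feature_fn.needs_training_graph else g
    X_train = np.concatenate(
        [feature_fn(feat_graph, train_pos), feature_fn(feat_graph, train_neg)]
    )
    y_train = np.concatenate([np.ones(n_train), np.zeros(n_train)])
    X_test = np.concatenate(
        [feature_fn(feat_graph, test_pos), feature_fn(feat_graph, eval_neg)]
    )
    y_test = np.concatenate([np.ones(n_test), np.zeros(n_test)])
    model = train_perceptron(
        X_train,
        y_train,
        config=perceptron,
        seed=derive_seed(seed, "model", replicate, feature_fn.name, train_sampler),
        standardize=feature_fn.standardize,
    )
    scores = model.predict_proba(X_test)
    rec = binary_metrics(scores, y_test, threshold=threshold)
    rec.update(
        replicate=replicate,
        feature=feature_fn.name,
        train_sampler=train_sampler,
        eval_sampler=eval_sampler,
    )
    return rec


def experiment_grid(
    g: Graph,
    positives,
    feature_fns,
    samplers=("uns", "dans"),
    replicates: int = 10,
    train_size: float = 0.75,
    seed: int = 0,
    remove_test_edges: bool = True,
    perceptron: PerceptronConfig | None = None,
    threshold: float = 0.5,
) -> CVResult:
    """Full cross of train-sampler x eval-sampler x feature.

    The positive train/test split is drawn once per replicate and shared by
    every condition (paired design); negatives are sampled per (replicate,
    phase, strategy) from seeds derived from the master seed, so conditions
    that share a strategy also share its negatives within a replicate.
    """
    positives = np.asarray(positives, dtype=np.int64).reshape(-1, 2)
    if len(positives) < 20:
        raise ValueError("need at least 20 positive edges")
    rows = []
    for r in range(replicates):
        train_pos, test_pos = _split_positives(
            positives, train_size, derive_rng(seed, "split", r)
        )
        train_graph = remove_edges(g, test_pos) if remove_test_edges else g
        for feature_fn in feature_fns:
            for train_sampler in samplers:
                for eval_sampler in samplers:
                    rows.append(
                        _run_condition(
                            g,
                            train_graph,
                            train_pos,
                            test_pos,
                            feature_fn,
                            train_sampler,
                            eval_sampler,
                            r,
                            seed,
                            perceptron,
                            threshold,
                        )
                    )
    df = pd.DataFrame(rows)[
        ["replicate", "feature", "train_sampler", "eval_sampler", *METRICS]
    ]
    return CVResult(per_replicate=df)


def monte_carlo_cv(
    g: Graph,
    positives,
    feature_fn: FeatureFunction,
    train_sampler: str = "uns",
    eval_sampler: str = "uns",
    replicates: int = 10,
    train_size: float = 0.75,
    seed: int = 0,
    remove_test_edges: bool = True,
    perceptron: PerceptronConfig | None = None,
) -> CVResult:
    """Repeated 75/25 holdout for a single sampler condition.

    Splits and negative seeds are derived exactly as in
    :func:`experiment_grid`, so results pair with grid runs at the same seed.
    """
    positives = np.asarray(positives, dtype=np.int64).reshape(-1, 2)
    if len(positives) < 20:
        raise ValueError("need at least 20 positive edges")
    rows = []
    for r in range(replicates):
        train_pos, test_pos = _split_positives(
            positives, train_size, derive_rng(seed, "split", r)
        )
        train_graph = remove_edges(g, test_pos) if remove_test_edges else g
        rows.append(
            _run_condition(
                g,
                train_graph,
                train_pos,
                test_pos,
                feature_fn,
                train_sampler,
                eval_sampler,
                r,
                seed,
                perceptron,
                0.5,
            )
        )
    df = pd.DataFrame(rows)[
        ["replicate", "feature", "train_sampler", "eval_sampler", *METRICS]
    ]
    return CVResult(per_replicate=df)


def inflation_test(result: CVResult, feature: str, train_sampler: str, metric: str = "mcc"):
    """One-sided paired t-test that eval=UNS scores exceed eval=DANS.

    Returns (mean difference, p-value) over replicates for one feature and
    one training sampler.
    """
    df = result.per_replicate
    sel = df[(df.feature == feature) & (df.train_sampler == train_sampler)]
    uns = sel[sel.eval_sampler == "uns"].sort_values("replicate")[metric].to_numpy()
    dans = sel[sel.eval_sampler == "dans"].sort_values("replicate")[metric].to_numpy()
    if len(uns) != len(dans) or len(uns) == 0:
        raise ValueError("need matched uns/dans replicates")
    diff = uns - dans
    if np.allclose(diff, diff[0]):
        p = 0.0 if diff[0] > 0 else 1.0
    else:
        p = float(stats.ttest_rel(uns, dans, alternative="greater").pvalue)
    return float(diff.mean()), p


def plot_metric_bars(result: CVResult, metric: str = "mcc", path=None, ax=None):
    """Horizontal mean ± std bars per (feature, train sampler, eval sampler)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    summary = result.summary()
    labels = [
        f"{f} | train={t} | eval={e}"
        for f, t, e in zip(summary.feature, summary.train_sampler, summary.eval_sampler)
    ]
    means = summary[f"{metric}_mean"].to_numpy()
    stds = np.nan_to_num(summary[f"{metric}_std"].to_numpy())
    if ax is None:
        _, ax = plt.subplots(figsize=(7, 0.4 * len(labels) + 1.5))
    y = np.arange(len(labels))
    ax.barh(y, means, xerr=stds, color="#4878b0")
    ax.set_yticks(y, labels, fontsize=8)
    ax.set_xlabel(metric.upper())
    ax.figure.tight_layout()
    if path is not None:
        ax.figure.savefig(path, dpi=120)
        plt.close(ax.figure)
    return ax
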