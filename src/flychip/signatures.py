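"""TSS chromatin-signature matrices, hierarchical clustering, and the small
feed-forward network predicting quantitative expression.

The network mirrors a deliberately tiny architecture — input layer (10 named
TSS windows or 6 marks x 19 positions = 114 inputs), two hidden layers of 2
and 3 logistic neurons, and a linear output on a 0-10 expression scale —
trained on a random half of the genes and evaluated on the held-out half,
repeated over independent runs. Input importance is a Garson-style
attribution: per input, the sum over all input->output paths of the products
of absolute weights, normalized to 1 and averaged over runs.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist
from sklearn.neural_network import MLPRegressor

from .metagene import DEFAULT_TSS_WINDOWS, tss_window_means
from .models import GeneModel
from .scoring import BinTrack

POSITION_OFFSETS = np.arange(-450, 451, 50)  # 19 positions


@dataclass
class SignatureMatrix:
    """Gene x feature matrix of z-standardized TSS chromatin scores."""

    data: pd.DataFrame
    mean: pd.Series
    std: pd.Series
    mode: str  # "windows" | "positions"


def build_signature_matrix(tracks: Dict[str, BinTrack], genes: Sequence[GeneModel],
                           mode: str = "windows",
                           marks: Optional[Sequence[str]] = None,
                           windows: Optional[dict] = None) -> SignatureMatrix:
    """Assemble the per-gene signature matrix.

    windows mode: the 10 named TSS windows; positions mode: every mark's mean
    score in 50-bp windows centred at 19 offsets from -450 to +450 bp.
    Zero-variance features are dropped with a warning; the rest are
    z-standardized.
    """
    if mode == "windows":
        raw = tss_window_means(tracks, genes, windows or DEFAULT_TSS_WINDOWS)
    elif mode == "positions":
        marks = list(marks) if marks is not None else sorted(tracks)
        win = {f"{m}@{off:+d}": (m, int(off) - 25, int(off) + 25)
               for m in marks for off in POSITION_OFFSETS}
        raw = tss_window_means(tracks, genes, win)
    else:
        raise ValueError("mode must be 'windows' or 'positions'")
    raw = raw.fillna(0.0)
    std = raw.std(ddof=0)
    dead = std[std == 0].index
    if len(dead):
        warnings.warn(f"dropping zero-variance features: {list(dead)}")
        raw = raw.drop(columns=dead)
        std = std.drop(dead)
    mean = raw.mean()
    z = (raw - mean) / std
    return SignatureMatrix(z, mean, std, mode)


@dataclass
class ClusterResult:
    labels: pd.Series
    linkage: np.ndarray
    summary: pd.DataFrame

    def to_newick(self) -> str:
        tree = hierarchy.to_tree(self.linkage)
        names = list(self.labels.index)

        def rec(node):
            if node.is_leaf():
                return names[node.id]
            return f"({rec(node.left)},{rec(node.right)}):{node.dist:g}"

        return rec(tree) + ";"


def cluster_genes(matrix: SignatureMatrix, k: int = 6, method: str = "average",
                  metric: str = "correlation",
                  expression: Optional[pd.Series] = None) -> ClusterResult:
    """Agglomerative clustering of genes by TSS signature, cut at k clusters.

    Expression (when given) is summarized per cluster for display but plays no
    role in the distance — the 'supervised' look of an expression-ordered
    heatmap is presentation, not metric.
    """
    df = matrix.data
    if k < 1 or k > len(df):
        raise ValueError("k must be between 1 and the number of genes")
    if len(df) == 1 or k == len(df):
        labels = pd.Series(np.arange(1, len(df) + 1) if k == len(df) else [1],
                           index=df.index)
        Z = np.empty((0, 4))
    else:
        d = pdist(df.to_numpy(), metric=metric)
        Z = hierarchy.linkage(d, method=method)
        labels = pd.Series(hierarchy.fcluster(Z, t=k, criterion="maxclust"),
                           index=df.index)
    rows = []
    for c in sorted(labels.unique()):
        members = labels.index[labels == c]
        row = {"cluster": c, "n_genes": len(members)}
        if expression is not None:
            e = expression.loc[members]
            row.update(mean_expression=float(e.mean()),
                       median_expression=float(e.median()))
        for col in df.columns:
            row[f"mean_{col}"] = float(df.loc[members, col].mean())
        rows.append(row)
    return ClusterResult(labels, Z, pd.DataFrame(rows).set_index("cluster"))


# ----------------------------------------------------------------------- ANN


@dataclass(frozen=True)
class ANNConfig:
    hidden: Tuple[int, int] = (2, 3)
    activation: str = "logistic"
    solver: str = "lbfgs"
    max_iter: int = 3000
    train_fraction: float = 0.5
    runs: int = 10
    seed: int = 0

    def __post_init__(self):
        if any(h <= 0 for h in self.hidden):
            raise ValueError("hidden layer sizes must be positive")
        if not 0 < self.train_fraction < 1:
            raise ValueError("train fraction must lie in (0, 1)")


@dataclass
class ANNResult:
    accuracies: List[float]
    pearson_r: List[float]
    importance: pd.DataFrame  # index feature; columns mean, sd
    run_importances: np.ndarray  # runs x features
    feature_names: List[str]
    models: list = field(default_factory=list, repr=False)

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean(self.accuracies))

    @property
    def mean_r(self) -> float:
        return float(np.mean(self.pearson_r))


def garson_importance(coefs: Sequence[np.ndarray]) -> np.ndarray:
    """Per-input attribution: sum over all input->output paths of products of
    absolute weights, normalized to sum to 1."""
    imp = np.abs(coefs[0])
    for w in coefs[1:]:
        imp = imp @ np.abs(w)
    imp = imp.ravel()
    total = imp.sum()
    if total <= 0:
        raise ValueError("untrained or degenerate network weights")
    return imp / total


def train_ann(matrix: SignatureMatrix, expression: pd.Series,
              config: ANNConfig = ANNConfig()) -> ANNResult:
    """Train/evaluate the expression predictor over independent half-split runs.

    Accuracy = 1 - mean|predicted - true| / 10 on the 0-10 expression scale;
    Pearson r on the held-out half is reported alongside. A run whose fit goes
    non-finite restarts with a fresh derived seed (at most 3 restarts).
    """
    X = matrix.data.to_numpy()
    y = expression.loc[matrix.data.index].to_numpy(dtype=float)
    n = len(y)
    rng = np.random.default_rng(config.seed)
    accuracies, rs, imps, models = [], [], [], []
    for run in range(config.runs):
        for attempt in range(4):
            sub_seed = int(rng.integers(0, 2**31 - 1))
            sub = np.random.default_rng(sub_seed)
            perm = sub.permutation(n)
            n_train = int(round(config.train_fraction * n))
            tr, te = perm[:n_train], perm[n_train:]
            model = MLPRegressor(hidden_layer_sizes=config.hidden,
                                 activation=config.activation, solver=config.solver,
                                 max_iter=config.max_iter, random_state=sub_seed)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model.fit(X[tr], y[tr])
            pred = model.predict(X[te])
            if np.all(np.isfinite(pred)):
                break
            warnings.warn(f"run {run}: non-finite prediction, restarting")
        else:
            raise RuntimeError(f"run {run}: training failed after 3 restarts")
        acc = 1.0 - float(np.mean(np.abs(pred - y[te]))) / 10.0
        if np.std(pred) > 0 and np.std(y[te]) > 0:
            r = float(np.corrcoef(pred, y[te])[0, 1])
        else:
            r = 0.0
        accuracies.append(acc)
        rs.append(r)
        imps.append(garson_importance(model.coefs_))
        models.append(model)
    run_imps = np.vstack(imps)
    names = list(matrix.data.columns)
    importance = pd.DataFrame({"mean": run_imps.mean(axis=0),
                               "sd": run_imps.std(axis=0, ddof=1) if len(imps) > 1
                               else np.zeros(run_imps.shape[1])}, index=names)
    return ANNResult(accuracies, rs, importance, run_imps, names, models)


def scale_expression(expr: pd.Series, lo: float = 0.0, hi: float = 10.0) -> pd.Series:
    """Min-max scale log1p expression onto the 0-10 output range."""
    v = np.log1p(expr.astype(float))
    span = v.max() - v.min()
    if span == 0:
        return pd.Series(np.full(len(v), (lo + hi) / 2), index=expr.index)
    return (v - v.min()) / span * (hi - lo) + lo
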