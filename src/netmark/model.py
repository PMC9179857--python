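"""Feature selection, kernel SVM training, Platt calibration, candidate ranking.

The classifier distinguishes known biomarker nodes from non-biomarker nodes
using their network-topology feature vectors.  A CART tree first selects the
informative features (rpart-style cost-complexity pruning on misclassification
risk, so pure-noise labels collapse to a root-only tree); a soft-margin C-SVC
with one of eight kernels is then trained on the selected, z-standardized
features; decision values are mapped to probabilities ("SVM points") by Platt
scaling with target smoothing; and every node scoring at least a probability
cutoff (default 0.99) is reported as a candidate biomarker.

Indefinite kernels (tanh, bessel, spline) are handled by the standard
workaround: the training Gram has its negative eigenvalues clipped to zero
before the QP, while prediction uses the unclipped kernel against the stored
support vectors.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier, DecisionTreeRegressor

from .errors import DegenerateLabelsError, SchemaError, ValidationError
from .evaluation import auc_statistic
from .kernels import KernelSpec, kernel_matrix, psd_clip
from .topology import FEATURE_NAMES

__all__ = [
    "LabeledSet",
    "TreeResult",
    "SVMModel",
    "select_features",
    "selected_or_all",
    "train_svm",
    "fit_svm",
    "calibrate_probabilities",
    "score_nodes",
    "predict_candidates",
    "compare_kernels",
]

POSITIVE_LABEL = "biomarker"
NEGATIVE_LABEL = "non_biomarker"
CUTOFF_DEFAULT = 0.99


@dataclass
class LabeledSet:
    """Node labels (biomarker / non_biomarker) with a train/test partition."""

    frame: pd.DataFrame  # index: node; columns: label, partition

    def __post_init__(self) -> None:
        missing = {"label", "partition"} - set(self.frame.columns)
        if missing:
            raise SchemaError(f"labeled set lacks columns: {sorted(missing)}")
        if self.frame.index.has_duplicates:
            raise ValidationError("a node may appear in only one partition")
        bad = set(self.frame["label"]) - {POSITIVE_LABEL, NEGATIVE_LABEL}
        if bad:
            raise ValidationError(f"unknown labels: {sorted(bad)}")
        bad = set(self.frame["partition"]) - {"train", "test"}
        if bad:
            raise ValidationError(f"unknown partitions: {sorted(bad)}")

    @classmethod
    def from_nodes(
        cls,
        positives: list[str],
        negatives: list[str],
        train_fraction: float = 0.7,
        seed: int = 0,
    ) -> "LabeledSet":
        """Stratified seeded train/test split of labeled node lists."""
        rng = np.random.default_rng(seed)
        rows = []
        for names, label in ((positives, POSITIVE_LABEL), (negatives, NEGATIVE_LABEL)):
            names = sorted(names)
            n_train = max(1, int(round(train_fraction * len(names))))
            if len(names) >= 2:
                n_train = min(n_train, len(names) - 1)
            picked = set(
                rng.choice(names, size=n_train, replace=False).tolist()
            )
            rows += [
                (g, label, "train" if g in picked else "test") for g in names
            ]
        frame = pd.DataFrame(rows, columns=["node", "label", "partition"]).set_index(
            "node"
        )
        return cls(frame)

    def nodes(self, partition: str | None = None) -> list[str]:
        if partition is None:
            return list(self.frame.index)
        return list(self.frame.index[self.frame["partition"] == partition])

    def y(self, nodes: list[str]) -> np.ndarray:
        """±1 vector (biomarker = +1) for the given nodes."""
        lab = self.frame["label"].reindex(nodes)
        if lab.isna().any():
            raise ValidationError("requested nodes missing from the labeled set")
        return np.where(lab.to_numpy() == POSITIVE_LABEL, 1, -1)


@dataclass
class TreeResult:
    """Pruned CART and the distinct split features, root first."""

    estimator: object
    selected_features: list[str]
    kept_nodes: np.ndarray  # boolean mask over tree nodes after pruning


def _node_risk(tree, flavor: str) -> np.ndarray:
    """Per-node risk: misclassification count (classification) or SSE (regression)."""
    wn = tree.weighted_n_node_samples
    if flavor == "classification":
        counts = tree.value[:, 0, :] * wn[:, None]
        return wn - counts.max(axis=1)
    return tree.impurity * wn


def _prune_rpart(tree, complexity: float, flavor: str) -> np.ndarray:
    """Weakest-link pruning at threshold complexity * risk(root).

    Returns a boolean mask: True where the node survives as part of the pruned
    structure (descendants of pruned internal nodes are dropped).
    """
    n = tree.node_count
    left, right = tree.children_left, tree.children_right
    risk = _node_risk(tree, flavor)
    alpha_star = complexity * max(risk[0], np.finfo(float).tiny)
    pruned = np.zeros(n, dtype=bool)  # internal nodes collapsed to leaves

    def is_leaf(i: int) -> bool:
        return left[i] == -1 or pruned[i]

    def subtree(i: int) -> tuple[float, int]:
        if is_leaf(i):
            return risk[i], 1
        rl, nl = subtree(left[i])
        rr, nr = subtree(right[i])
        return rl + rr, nl + nr

    while True:
        best_g, best_i = np.inf, -1
        stack = [0]
        while stack:
            i = stack.pop()
            if is_leaf(i):
                continue
            r_sub, n_leaves = subtree(i)
            g = (risk[i] - r_sub) / (n_leaves - 1) if n_leaves > 1 else np.inf
            if g < best_g - 1e-12 or (abs(g - best_g) <= 1e-12 and i < best_i):
                best_g, best_i = g, i
            stack.extend([left[i], right[i]])
        if best_i < 0 or best_g > alpha_star + 1e-12:
            break
        pruned[best_i] = True

    kept = np.zeros(n, dtype=bool)
    stack = [0]
    while stack:
        i = stack.pop()
        kept[i] = True
        if not is_leaf(i):
            stack.extend([left[i], right[i]])
    return kept


def select_features(
    features: pd.DataFrame,
    labels: LabeledSet,
    min_split: int = 20,
    complexity: float = 0.01,
    flavor: str = "classification",
    seed: int = 0,
) -> TreeResult:
    """CART feature selection on the training partition.

    Grows a Gini-split classification tree (or a squared-error regression tree
    on the 0/1 target when ``flavor='regression'``), prunes it rpart-style at
    cost-complexity ``complexity`` measured on misclassification / SSE risk
    relative to the root, and reports the distinct split features of the
    pruned tree in order of first appearance (root first).
    """
    if flavor not in ("classification", "regression"):
        raise ValidationError("flavor must be 'classification' or 'regression'")
    train = labels.nodes("train")
    y = labels.y(train)
    if len(np.unique(y)) < 2 or min((y == 1).sum(), (y == -1).sum()) < 2:
        raise DegenerateLabelsError("need >= 2 training nodes per class")
    cols = [c for c in FEATURE_NAMES if c in features.columns] or list(features.columns)
    X = features.loc[train, cols].to_numpy(float)

    min_leaf = max(1, int(round(min_split / 3)))  # rpart's minbucket convention
    if flavor == "classification":
        est = DecisionTreeClassifier(
            criterion="gini", min_samples_split=min_split,
            min_samples_leaf=min_leaf, random_state=seed,
        ).fit(X, (y == 1).astype(int))
    else:
        est = DecisionTreeRegressor(
            criterion="squared_error", min_samples_split=min_split,
            min_samples_leaf=min_leaf, random_state=seed,
        ).fit(X, (y == 1).astype(float))

    kept = _prune_rpart(est.tree_, complexity, flavor)

    selected: list[str] = []
    tree = est.tree_
    stack = [0]
    order = []
    while stack:  # preorder, root first
        i = stack.pop()
        order.append(i)
        l, r = tree.children_left[i], tree.children_right[i]
        if l != -1 and kept[l] and kept[r]:
            stack.extend([r, l])
    for i in order:
        l = tree.children_left[i]
        if l != -1 and kept[l]:
            name = cols[tree.feature[i]]
            if name not in selected:
                selected.append(name)
    return TreeResult(estimator=est, selected_features=selected, kept_nodes=kept)


def selected_or_all(result: TreeResult) -> list[str]:
    """Selected features, falling back to the full battery when the tree is a stump."""
    if result.selected_features:
        return list(result.selected_features)
    warnings.warn(
        "pruned tree has no splits; falling back to all topology features",
        stacklevel=2,
    )
    return list(FEATURE_NAMES)


@dataclass
class SVMModel:
    """Everything needed to reproduce the decision function and SVM point."""

    kernel: KernelSpec
    dual_coef: np.ndarray
    bias: float
    C: float
    support_indices: np.ndarray
    support_vectors: np.ndarray | None = None
    platt_a: float | None = None
    platt_b: float | None = None
    feature_names: list[str] = field(default_factory=list)
    mean_: np.ndarray | None = None
    scale_: np.ndarray | None = None

    def standardize(self, X: np.ndarray) -> np.ndarray:
        if self.mean_ is None or self.scale_ is None:
            return np.asarray(X, dtype=float)
        return (np.asarray(X, dtype=float) - self.mean_) / self.scale_

    def decision_function(self, X_std: np.ndarray) -> np.ndarray:
        """f(x) = sum_i alpha_i y_i k(sv_i, x) + b, with the unclipped kernel."""
        if self.support_vectors is None:
            raise ValidationError("model stores no support vectors")
        G = kernel_matrix(np.atleast_2d(X_std), self.support_vectors, self.kernel)
        return G @ self.dual_coef + self.bias

    def point(self, X_std: np.ndarray) -> np.ndarray:
        """Calibrated probability of being a biomarker (the SVM point)."""
        if self.platt_a is None or self.platt_b is None:
            raise ValidationError("model is not calibrated")
        z = np.clip(
            self.platt_a * self.decision_function(X_std) + self.platt_b, -500, 500
        )
        return 1.0 / (1.0 + np.exp(z))

    def to_dict(self) -> dict:
        return {
            "kernel": {
                "name": self.kernel.name,
                "sigma": self.kernel.sigma,
                "degree": self.kernel.degree,
                "nu": self.kernel.nu,
                "scale": self.kernel.scale,
                "offset": self.kernel.offset,
            },
            "dual_coef": self.dual_coef.tolist(),
            "bias": self.bias,
            "C": self.C,
            "support_indices": self.support_indices.tolist(),
            "support_vectors": None
            if self.support_vectors is None
            else self.support_vectors.tolist(),
            "platt_a": self.platt_a,
            "platt_b": self.platt_b,
            "feature_names": list(self.feature_names),
            "mean": None if self.mean_ is None else self.mean_.tolist(),
            "scale": None if self.scale_ is None else self.scale_.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SVMModel":
        return cls(
            kernel=KernelSpec(**d["kernel"]),
            dual_coef=np.asarray(d["dual_coef"], float),
            bias=float(d["bias"]),
            C=float(d["C"]),
            support_indices=np.asarray(d["support_indices"], int),
            support_vectors=None
            if d["support_vectors"] is None
            else np.asarray(d["support_vectors"], float),
            platt_a=d["platt_a"],
            platt_b=d["platt_b"],
            feature_names=list(d["feature_names"]),
            mean_=None if d["mean"] is None else np.asarray(d["mean"], float),
            scale_=None if d["scale"] is None else np.asarray(d["scale"], float),
        )

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1, sort_keys=True)

    @classmethod
    def load(cls, path) -> "SVMModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def train_svm(
    gram: np.ndarray,
    labels: np.ndarray,
    C: float = 1.0,
    kernel: KernelSpec | None = None,
    clip: bool = True,
) -> SVMModel:
    """Solve the soft-margin C-SVC dual on a precomputed (training) Gram.

    The Gram is symmetrized and, if ``clip``, eigenvalue-clipped to PSD before
    the QP (required for indefinite kernels).  ``dual_coef`` holds alpha_i*y_i
    over the support rows; |alpha_i| <= C.
    """
    G = np.asarray(gram, dtype=float)
    if G.ndim != 2 or G.shape[0] != G.shape[1]:
        raise ValidationError("training Gram must be square")
    if np.abs(G - G.T).max() > 1e-6:
        raise ValidationError("training Gram must be symmetric")
    y = np.asarray(labels)
    if len(np.unique(y)) < 2:
        raise DegenerateLabelsError("both classes must be present for SVM training")
    if not C > 0:
        raise ValidationError("C must be positive")
    G_fit = psd_clip(G) if clip else (G + G.T) / 2.0
    svc = SVC(kernel="precomputed", C=C, tol=1e-6)
    svc.fit(G_fit, y)
    return SVMModel(
        kernel=kernel if kernel is not None else KernelSpec("linear"),
        dual_coef=svc.dual_coef_.ravel().copy(),
        bias=float(svc.intercept_[0]),
        C=float(C),
        support_indices=svc.support_.copy(),
    )


def calibrate_probabilities(
    decisions: np.ndarray, labels: np.ndarray, max_iter: int = 100
) -> tuple[float, float]:
    """Platt scaling with target smoothing: fit P(y=1|f) = 1/(1+exp(a f + b)).

    Uses the regularized maximum-likelihood targets t+ = (N+ + 1)/(N+ + 2) and
    t- = 1/(N- + 2) and a damped Newton iteration on the cross-entropy.
    """
    f = np.asarray(decisions, dtype=float)
    if not np.isfinite(f).all():
        raise ValidationError("decision values must be finite")
    y = np.asarray(labels)
    pos = y == 1
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise DegenerateLabelsError("both classes required for calibration")
    t = np.where(pos, (n_pos + 1.0) / (n_pos + 2.0), 1.0 / (n_neg + 2.0))

    a, b = 0.0, float(np.log((n_neg + 1.0) / (n_pos + 1.0)))

    def objective(a_: float, b_: float) -> float:
        # NLL = sum log(1 + e^z) - (1 - t) z   with z = a f + b
        z = a_ * f + b_
        return float(np.sum(np.logaddexp(0.0, z) - (1.0 - t) * z))

    sigma = 1e-12
    for _ in range(max_iter):
        z = np.clip(a * f + b, -500, 500)
        p = 1.0 / (1.0 + np.exp(z))  # P(y=1)
        d = t - p  # dNLL/dz
        g1 = float(np.sum(d * f))
        g2 = float(np.sum(d))
        if abs(g1) < 1e-10 and abs(g2) < 1e-10:
            break
        w = p * (1.0 - p)
        h11 = float(np.sum(w * f * f)) + sigma
        h22 = float(np.sum(w)) + sigma
        h12 = float(np.sum(w * f))
        det = h11 * h22 - h12 * h12
        da = -(h22 * g1 - h12 * g2) / det
        db = -(-h12 * g1 + h11 * g2) / det
        # backtracking line search on the objective
        step, base = 1.0, objective(a, b)
        while step > 1e-10:
            if objective(a + step * da, b + step * db) < base + 1e-12:
                a += step * da
                b += step * db
                break
            step /= 2.0
        else:
            break
    return float(a), float(b)


def fit_svm(
    features: pd.DataFrame,
    labels: LabeledSet,
    spec: KernelSpec,
    C: float = 1.0,
    feature_names: list[str] | None = None,
) -> SVMModel:
    """Standardize, train and calibrate an SVM on the training partition.

    Standardization parameters come from the training rows only; test/predict
    rows are transformed with those stored parameters (no leakage).
    """
    cols = list(feature_names) if feature_names else list(features.columns)
    missing = set(cols) - set(features.columns)
    if missing:
        raise SchemaError(f"feature matrix lacks columns: {sorted(missing)}")
    train = labels.nodes("train")
    X = features.loc[train, cols].to_numpy(float)
    y = labels.y(train)

    mean = X.mean(axis=0)
    scale = X.std(axis=0, ddof=0)
    scale[scale == 0] = 1.0
    Xs = (X - mean) / scale

    gram = kernel_matrix(Xs, Xs, spec)
    model = train_svm(gram, y, C=C, kernel=spec)
    model.feature_names = cols
    model.mean_ = mean
    model.scale_ = scale
    model.support_vectors = Xs[model.support_indices]
    decisions = model.decision_function(Xs)
    model.platt_a, model.platt_b = calibrate_probabilities(decisions, y)
    return model


def score_nodes(model: SVMModel, features: pd.DataFrame) -> pd.DataFrame:
    """SVM point for every node, sorted by point descending (ties: node id)."""
    missing = set(model.feature_names) - set(features.columns)
    if missing:
        raise SchemaError(f"feature matrix lacks columns: {sorted(missing)}")
    X = model.standardize(features[model.feature_names].to_numpy(float))
    table = pd.DataFrame(
        {
            "point": model.point(X),
            "decision": model.decision_function(X),
        },
        index=features.index.rename("node"),
    )
    order = np.lexsort((table.index.astype(str), -table["point"].to_numpy()))
    table = table.iloc[order]
    table["rank"] = np.arange(1, len(table) + 1)
    return table


def predict_candidates(
    model: SVMModel,
    features: pd.DataFrame,
    cutoff: float = CUTOFF_DEFAULT,
    exclude: set[str] | None = None,
) -> pd.DataFrame:
    """Nodes whose SVM point reaches the probability cutoff, ranked.

    ``exclude`` removes already-known biomarkers from the candidate list.
    """
    if not 0.0 <= cutoff <= 1.0:
        raise ValidationError("cutoff must be a probability in [0, 1]")
    table = score_nodes(model, features)
    keep = table["point"] >= cutoff
    if exclude:
        keep &= ~table.index.isin(sorted(exclude))
    out = table.loc[keep, ["point", "decision"]].copy()
    out["rank"] = np.arange(1, len(out) + 1)
    return out


def compare_kernels(
    features: pd.DataFrame,
    labels: LabeledSet,
    specs: list[KernelSpec],
    C: float = 1.0,
    feature_names: list[str] | None = None,
) -> pd.DataFrame:
    """Test-set ROC AUC of one SVM per kernel spec; best kernel first is argmax.

    AUC is computed on raw decision values (any monotone calibration leaves it
    unchanged) and is NOT orientation-flipped, so a kernel that ranks
    biomarkers below non-biomarkers scores below 0.5.
    """
    test = labels.nodes("test")
    if len(np.unique(labels.y(labels.nodes("train")))) < 2:
        raise DegenerateLabelsError("training partition needs both classes")
    if len(np.unique(labels.y(test))) < 2:
        raise DegenerateLabelsError("test partition needs both classes")
    rows = []
    for spec in specs:
        model = fit_svm(features, labels, spec, C=C, feature_names=feature_names)
        X = model.standardize(
            features.loc[test, model.feature_names].to_numpy(float)
        )
        dec = model.decision_function(X)
        rows.append((spec.name, auc_statistic(dec, labels.y(test) == 1)))
    table = pd.DataFrame(rows, columns=["kernel", "auc"])
    table["best"] = table["auc"] == table["auc"].max()
    return table
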