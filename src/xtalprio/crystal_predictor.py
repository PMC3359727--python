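"""Recursive regression partition tree predicting the diffraction score.

Crystallization outcome is recorded on an ordinal 0-6 diffraction score:
0 no crystals; 1 crystals but no diffraction; 2 diffraction worse than
10.00 A; 3 10.00-4.01 A; 4 4.00-2.81 A; 5 2.80-2.01 A; 6 2.00 A or better.

The predictor is a CART-style regression tree over six features per sample
(DSF fluorescence ratio, yield, SEC single-Gaussian residual, DLS Pmaj,
monomer MW, longest disorder stretch).  Training greedily picks the binary
split maximizing the reduction in the sum of squared score deviations, with
thresholds at midpoints between adjacent observed values; each leaf predicts
the mean training score of the samples routed to it and keeps the full
outcome histogram so users can judge the spread, not just the mean.

Missing features route to the child that received more training samples
(majority-child rule); the published trees of this kind are not reproduced
here, so a JSON tree-definition format lets users encode any external tree
verbatim instead of training one.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

FEATURE_NAMES = ["r_dsf", "yield_score", "r_sec", "p_maj", "mw_mono", "l_dis"]

#: diffraction-score bins by best resolution (A); each bin includes its endpoints
RESOLUTION_BINS = [(2.00, 6), (2.80, 5), (4.00, 4), (10.00, 3)]

#: interpretation bands over the predicted mean score (lower bound -> text)
INTERPRETATION_BANDS = [
    (4.5, "likely to form crystals with diffraction of 2.8 Å or better"),
    (3.0, "likely to form crystals that diffract"),
    (1.0, "may form crystals; diffraction quality uncertain"),
    (0.0, "not likely to form crystals"),
]

#: advice emitted for an unfavorable split on each feature
SUGGESTION_RULES = {
    "l_dis": "Truncate the construct to remove predicted disorder "
             "(long disordered stretches resist crystallization).",
    "r_dsf": "High 30 °C fluorescence suggests partial unfolding or dye "
             "binding; try stabilizing buffers, ligands or a homolog.",
    "yield_score": "Modify expression and purification protocols to improve "
                   "the yield.",
    "r_sec": "Modify expression and purification protocols to improve the "
             "SEC profile (reduce aggregates/heterogeneity).",
    "p_maj": "Polydisperse DLS: optimize buffer/additives or remove "
             "aggregates to increase the major-peak fraction.",
    "mw_mono": "Consider alternative construct boundaries or domain "
               "truncations to change the monomer size.",
}

SCREENING_ADVICE = (
    "Sample properties predict success: try additional crystallization "
    "screens and high-throughput screening facilities."
)


def resolution_to_score(outcome: str | float) -> int:
    """Map a crystallization outcome to the 0-6 diffraction score.

    ``outcome`` is 'no_crystals', 'no_diffraction', or the best diffraction
    resolution in Angstrom.  Printed resolution ranges include their
    endpoints: 10.00 A -> 3, 4.00 A -> 4, 2.80 A -> 5, 2.00 A -> 6.
    """
    if isinstance(outcome, str):
        key = outcome.strip().lower().replace(" ", "_")
        if key == "no_crystals":
            return 0
        if key == "no_diffraction":
            return 1
        try:
            outcome = float(key)
        except ValueError:
            raise ValueError(f"unknown outcome {outcome!r}")
    res = float(outcome)
    if res <= 0:
        raise ValueError("resolution must be positive")
    for bound, score in RESOLUTION_BINS:
        if res <= bound:
            return score
    return 2


@dataclass
class TreeNode:
    # internal nodes
    feature: str | None = None
    threshold: float | None = None
    left: "TreeNode | None" = None    # feature <= threshold
    right: "TreeNode | None" = None   # feature > threshold
    missing_left: bool = True         # majority-child route for missing values
    # every node keeps its routed-sample statistics
    mean: float = 0.0
    n: int = 0
    train_hist: list[int] = field(default_factory=lambda: [0] * 7)
    test_hist: list[int] = field(default_factory=lambda: [0] * 7)

    @property
    def is_leaf(self) -> bool:
        return self.feature is None


@dataclass
class RegressionTree:
    root: TreeNode
    min_leaf: int = 5
    max_depth: int = 5
    feature_names: list[str] = field(default_factory=lambda: list(FEATURE_NAMES))

    def route(self, fv: dict[str, float | None]) -> tuple[TreeNode, list[dict]]:
        """Route a feature dict to a leaf; returns (leaf, path records)."""
        node = self.root
        path: list[dict] = []
        while not node.is_leaf:
            x = fv.get(node.feature)
            imputed = bool(x is None or (isinstance(x, float) and np.isnan(x)))
            if imputed:
                go_left = node.missing_left
            else:
                go_left = x <= node.threshold
            taken = node.left if go_left else node.right
            other = node.right if go_left else node.left
            if taken.mean > other.mean:
                favorable = True
            elif taken.mean < other.mean:
                favorable = False
            else:
                favorable = None  # equal child means: neutral branch
            path.append({
                "feature": node.feature,
                "threshold": node.threshold,
                "direction": "<=" if go_left else ">",
                "favorable": favorable,
                "imputed": imputed,
            })
            node = taken
        return node, path

    def leaves(self) -> list[TreeNode]:
        out, stack = [], [self.root]
        while stack:
            n = stack.pop()
            if n.is_leaf:
                out.append(n)
            else:
                stack.extend([n.left, n.right])
        return out

    # -- JSON tree-definition format ------------------------------------
    def to_json(self) -> str:
        def enc(n: TreeNode) -> dict:
            d = {"mean": n.mean, "n": n.n, "train_hist": n.train_hist,
                 "test_hist": n.test_hist}
            if not n.is_leaf:
                d.update(feature=n.feature, threshold=n.threshold,
                         missing_left=n.missing_left,
                         left=enc(n.left), right=enc(n.right))
            return d
        return json.dumps({
            "format": "xtalprio-tree", "version": 1,
            "feature_names": self.feature_names,
            "min_leaf": self.min_leaf, "max_depth": self.max_depth,
            "root": enc(self.root),
        }, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "RegressionTree":
        doc = json.loads(text)
        if doc.get("format") != "xtalprio-tree":
            raise ValueError("not an xtalprio tree-definition document")

        def dec(d: dict) -> TreeNode:
            n = TreeNode(mean=float(d["mean"]), n=int(d.get("n", 0)),
                         train_hist=list(d.get("train_hist", [0] * 7)),
                         test_hist=list(d.get("test_hist", [0] * 7)))
            if "feature" in d:
                n.feature = d["feature"]
                n.threshold = float(d["threshold"])
                n.missing_left = bool(d.get("missing_left", True))
                n.left = dec(d["left"])
                n.right = dec(d["right"])
            return n
        return cls(root=dec(doc["root"]),
                   min_leaf=int(doc.get("min_leaf", 5)),
                   max_depth=int(doc.get("max_depth", 5)),
                   feature_names=list(doc.get("feature_names", FEATURE_NAMES)))


def _hist(scores: np.ndarray) -> list[int]:
    h = [0] * 7
    for s in scores:
        h[int(round(s))] += 1
    return h


def _best_split(X: np.ndarray, y: np.ndarray, feat_idx: int, min_leaf: int):
    """Best midpoint threshold for one feature; returns (gain, threshold,
    missing_left) or None.  Missing samples go to the majority child."""
    col = X[:, feat_idx]
    present = ~np.isnan(col)
    if present.sum() < 2:
        return None
    vals = np.unique(col[present])
    if len(vals) < 2:
        return None
    sse_parent = float(np.sum((y - y.mean()) ** 2))
    best = None
    for lo, hi in zip(vals[:-1], vals[1:]):
        thr = (lo + hi) / 2.0
        left_present = present & (col <= thr)
        right_present = present & (col > thr)
        missing_left = left_present.sum() >= right_present.sum()
        left = left_present | (~present if missing_left else np.zeros_like(present))
        right = ~left
        nl, nr = int(left.sum()), int(right.sum())
        if nl < min_leaf or nr < min_leaf:
            continue
        sse = (float(np.sum((y[left] - y[left].mean()) ** 2))
               + float(np.sum((y[right] - y[right].mean()) ** 2)))
        gain = sse_parent - sse
        if best is None or gain > best[0] + 1e-12:
            best = (gain, thr, missing_left)
    return best


def _grow(X, y, ytest, Xtest, min_leaf, max_depth, depth, feature_names):
    node = TreeNode(mean=float(y.mean()), n=len(y), train_hist=_hist(y))
    if Xtest is not None and len(ytest):
        node.test_hist = _hist(ytest)
    if depth >= max_depth or len(y) < 2 * min_leaf or np.ptp(y) == 0:
        return node
    best = None
    for j in range(X.shape[1]):
        cand = _best_split(X, y, j, min_leaf)
        if cand and (best is None or cand[0] > best[0] + 1e-12):
            best = (*cand, j)
    if best is None or best[0] <= 1e-12:
        return node
    gain, thr, missing_left, j = best
    col = X[:, j]
    present = ~np.isnan(col)
    left = (present & (col <= thr)) | (~present & missing_left)
    if Xtest is not None and len(ytest):
        tcol = Xtest[:, j]
        tpresent = ~np.isnan(tcol)
        tleft = (tpresent & (tcol <= thr)) | (~tpresent & missing_left)
    else:
        tleft = np.zeros(0, dtype=bool)
        Xtest = Xtest if Xtest is not None else None
    node.feature = feature_names[j]
    node.threshold = float(thr)
    node.missing_left = bool(missing_left)
    node.left = _grow(X[left], y[left],
                      ytest[tleft] if len(tleft) else ytest,
                      Xtest[tleft] if Xtest is not None and len(tleft) else None,
                      min_leaf, max_depth, depth + 1, feature_names)
    node.right = _grow(X[~left], y[~left],
                       ytest[~tleft] if len(tleft) else ytest,
                       Xtest[~tleft] if Xtest is not None and len(tleft) else None,
                       min_leaf, max_depth, depth + 1, feature_names)
    return node


def _cohort_to_arrays(cohort, feature_names):
    X = np.full((len(cohort), len(feature_names)), np.nan)
    y = np.empty(len(cohort))
    for i, (fv, score) in enumerate(cohort):
        fvd = fv.as_dict() if hasattr(fv, "as_dict") else dict(fv)
        for j, name in enumerate(feature_names):
            v = fvd.get(name)
            if v is not None:
                X[i, j] = v
        y[i] = float(int(score))
    return X, y


class DiffractionTreeModel:
    """CART regression-tree model of diffraction score vs the feature vector.

    Parameters
    ----------
    cohort : list of (feature mapping, score 0-6)
        Feature mapping is a dict or FeatureVector; missing values are None.
    min_leaf, max_depth : stopping parameters (defaults 5 and 5).
    """

    def __init__(self, cohort, min_leaf: int = 5, max_depth: int = 5,
                 feature_names=None):
        self.feature_names = list(feature_names or FEATURE_NAMES)
        if len(cohort) < 2 * min_leaf and len(cohort) < 2:
            raise ValueError("cohort too small to train on")
        self.cohort = list(cohort)
        self.min_leaf = min_leaf
        self.max_depth = max_depth

    @classmethod
    def from_dataframe(cls, df, score_column: str = "score", **kw):
        """Build from a DataFrame with one feature column per name + a score."""
        names = kw.pop("feature_names", None) or [
            c for c in FEATURE_NAMES if c in df.columns
        ]
        cohort = []
        for _, row in df.iterrows():
            fv = {n: (None if np.isnan(row[n]) else float(row[n])) for n in names}
            cohort.append((fv, int(row[score_column])))
        return cls(cohort, feature_names=names, **kw)

    def fit(self, test_cohort=None) -> "DiffractionTreeResults":
        X, y = _cohort_to_arrays(self.cohort, self.feature_names)
        if test_cohort:
            Xt, yt = _cohort_to_arrays(test_cohort, self.feature_names)
        else:
            Xt, yt = None, np.zeros(0)
        root = _grow(X, y, yt, Xt, self.min_leaf, self.max_depth, 0,
                     self.feature_names)
        tree = RegressionTree(root=root, min_leaf=self.min_leaf,
                              max_depth=self.max_depth,
                              feature_names=self.feature_names)
        return DiffractionTreeResults(model=self, tree=tree, X=X, y=y)


@dataclass
class DiffractionTreeResults:
    """Fitted regression tree with training diagnostics."""

    model: DiffractionTreeModel
    tree: RegressionTree
    X: np.ndarray
    y: np.ndarray

    @property
    def train_mse(self) -> float:
        preds = np.array([
            self.tree.route({n: (None if np.isnan(v) else float(v))
                             for n, v in zip(self.tree.feature_names, row)})[0].mean
            for row in self.X
        ])
        return float(np.mean((preds - self.y) ** 2))

    @property
    def n_leaves(self) -> int:
        return len(self.tree.leaves())

    def predict(self, fv) -> "Prediction":
        return predict(self.tree, fv)

    def summary(self) -> str:
        lines = [
            "Diffraction-score regression tree",
            f"  n = {len(self.y)}   leaves = {self.n_leaves}   "
            f"training MSE = {self.train_mse:.4f}",
            f"  min leaf = {self.tree.min_leaf}   max depth = {self.tree.max_depth}",
        ]

        def walk(n: TreeNode, indent: int, label: str) -> None:
            pad = "  " * (indent + 1)
            if n.is_leaf:
                lines.append(f"{pad}{label}leaf: mean {n.mean:.3f} (n={n.n})")
            else:
                lines.append(
                    f"{pad}{label}{n.feature} <= {n.threshold:.6g} "
                    f"(missing -> {'left' if n.missing_left else 'right'})"
                )
                walk(n.left, indent + 1, "L ")
                walk(n.right, indent + 1, "R ")
        walk(self.tree.root, 0, "")
        return "\n".join(lines)


def train_tree(cohort, min_leaf: int = 5, max_depth: int = 5,
               test_cohort=None, feature_names=None) -> RegressionTree:
    """Train a CART regression tree on (features, score) pairs."""
    res = DiffractionTreeModel(
        cohort, min_leaf=min_leaf, max_depth=max_depth,
        feature_names=feature_names,
    ).fit(test_cohort=test_cohort)
    return res.tree


@dataclass
class Prediction:
    mean_score: float
    interpretation: str
    train_hist: list[int]
    test_hist: list[int]
    path: list[dict]
    leaf_n: int

    @property
    def is_top_category(self) -> bool:
        return self.mean_score >= INTERPRETATION_BANDS[0][0]

    def report(self) -> str:
        lines = [
            f"Predicted mean diffraction score: {self.mean_score:.2f}",
            f"Interpretation: {self.interpretation}",
            f"Outcome distribution (training, n={self.leaf_n}):",
            "  score : " + "  ".join(str(s) for s in range(7)),
            "  train : " + "  ".join(str(c) for c in self.train_hist),
        ]
        if any(self.test_hist):
            lines.append("  test  : " + "  ".join(str(c) for c in self.test_hist))
        lines.append("Decision path:")
        if not self.path:
            lines.append("  (single-leaf tree: no splits)")
        for step in self.path:
            tag = {True: "+", False: "-", None: "="}[step["favorable"]]
            imput = "  [value missing; majority-child route]" if step["imputed"] else ""
            lines.append(
                f"  [{tag}] {step['feature']} {step['direction']} "
                f"{step['threshold']:.6g}{imput}"
            )
        return "\n".join(lines)


def interpret_score(mean_score: float, bands=None) -> str:
    for lo, text in (bands or INTERPRETATION_BANDS):
        if mean_score >= lo:
            return text
    return INTERPRETATION_BANDS[-1][1]


def predict(tree: RegressionTree, fv) -> Prediction:
    """Route one feature vector through the tree and assemble the prediction."""
    fvd = fv.as_dict() if hasattr(fv, "as_dict") else dict(fv)
    if fvd.get("mw_mono") is None and "mw_mono" in tree.feature_names:
        raise ValueError("monomer MW is mandatory for prediction (add a sequence)")
    leaf, path = tree.route(fvd)
    return Prediction(
        mean_score=leaf.mean,
        interpretation=interpret_score(leaf.mean),
        train_hist=list(leaf.train_hist),
        test_hist=list(leaf.test_hist),
        path=path,
        leaf_n=leaf.n,
    )


def suggestions(pred: Prediction, fv=None, no_crystals_yet: bool = False,
                rules=None) -> list[str]:
    """Advice items from the unfavorable splits on the decision path.

    A sample already in the top category that has produced no crystals gets
    screening-resource advice instead of protocol changes.
    """
    rules = rules or SUGGESTION_RULES
    if pred.is_top_category:
        return [SCREENING_ADVICE] if no_crystals_yet else []
    out: list[str] = []
    for step in pred.path:
        if step["favorable"] is False:
            advice = rules.get(step["feature"])
            if advice and advice not in out:
                out.append(advice)
    return out
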