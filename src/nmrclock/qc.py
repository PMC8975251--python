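"""Methylation-profile QC: random-forest label prediction and
correlation-based hierarchical clustering.

Tissue and sex are so strongly encoded in methylation profiles that a
random forest predicts them with near-zero out-of-bag (OOB) error on
real arrays; these predictors double as platemap validators. The
clustering check uses average-linkage hierarchical clustering on the
inter-array correlation distance (1 - Pearson r between sample
profiles), cut at a fixed height (default 0.04) — well-behaved studies
cluster by tissue.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from sklearn.ensemble import RandomForestClassifier

from .core_io import BetaMatrix, ValidationError

__all__ = ["OOBReport", "rf_label_predictor", "cluster_samples", "linkage_to_newick"]


@dataclass
class OOBReport:
    """Out-of-bag performance of a random-forest label predictor."""

    oob_error: float
    predicted: pd.Series  # per-sample OOB predicted label
    confusion: pd.DataFrame  # rows = true label, cols = predicted

    @property
    def n_misclassified(self) -> int:
        total = int(self.confusion.to_numpy().sum())
        correct = int(np.trace(self.confusion.reindex(columns=self.confusion.index, fill_value=0).to_numpy()))
        return total - correct


def rf_label_predictor(
    betas, labels, n_trees: int = 500, seed: int = 0, max_features: str = "sqrt"
) -> OOBReport:
    """Random forest on CpG features with OOB error estimation.

    OOB predictions come from trees whose bootstrap sample excluded the
    sample in question, so the error is an honest estimate without a
    held-out set.
    """
    X = betas.values if isinstance(betas, BetaMatrix) else pd.DataFrame(betas)
    y = pd.Series(list(labels), index=X.index)
    classes = sorted(y.unique())
    if len(classes) < 2:
        raise ValidationError("need >= 2 classes")
    small = y.value_counts()
    if (small < 3).any():
        raise ValidationError(f"classes with < 3 samples: {dict(small[small < 3])}")

    rf = RandomForestClassifier(
        n_estimators=n_trees,
        max_features=max_features,
        oob_score=True,
        bootstrap=True,
        random_state=seed,
    )
    rf.fit(X.to_numpy(), y.to_numpy())
    votes = rf.oob_decision_function_
    pred = np.array(rf.classes_)[np.argmax(votes, axis=1)]
    # a sample in every bootstrap (vanishingly rare) has no OOB vote
    no_vote = votes.sum(axis=1) == 0
    if no_vote.any():
        pred[no_vote] = rf.predict(X.to_numpy()[no_vote])
    predicted = pd.Series(pred, index=X.index, name="oob_predicted")
    confusion = pd.crosstab(y, predicted).reindex(index=classes, columns=classes, fill_value=0)
    oob_error = float((predicted != y).mean())
    return OOBReport(oob_error=oob_error, predicted=predicted, confusion=confusion)


def cluster_samples(betas, cut_height: float = 0.04):
    """Average-linkage clustering on 1 - Pearson inter-array correlation.

    Returns (linkage matrix, cluster labels aligned to sample order,
    distance matrix as DataFrame). Samples with a constant profile have
    an undefined correlation and are rejected by name.
    """
    X = betas.values if isinstance(betas, BetaMatrix) else pd.DataFrame(betas)
    if X.shape[0] < 3:
        raise ValidationError("need >= 3 samples to cluster")
    arr = X.to_numpy()
    sd = arr.std(axis=1)
    if (sd == 0).any():
        bad = list(X.index[sd == 0])[:5]
        raise ValidationError(f"constant sample profiles (undefined correlation): {bad}")
    corr = np.corrcoef(arr)
    dist = 1.0 - corr
    np.fill_diagonal(dist, 0.0)
    dist = (dist + dist.T) / 2  # enforce exact symmetry for squareform
    Z = hierarchy.average(squareform(dist, checks=False))
    labels = hierarchy.fcluster(Z, t=cut_height, criterion="distance")
    dist_df = pd.DataFrame(dist, index=X.index, columns=X.index)
    return Z, pd.Series(labels, index=X.index, name="cluster"), dist_df


def linkage_to_newick(Z: np.ndarray, leaf_names) -> str:
    """Render a scipy linkage as a Newick string (for eyeballing trees)."""
    tree = hierarchy.to_tree(Z)
    names = list(leaf_names)

    def walk(node, parent_dist):
        length = max(parent_dist - node.dist, 0.0)
        if node.is_leaf():
            return f"{names[node.id]}:{length:g}"
        left = walk(node.left, node.dist)
        right = walk(node.right, node.dist)
        return f"({left},{right}):{length:g}"

    return walk(tree, tree.dist) + ";"
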