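"""Stratify genes by model error with a pruned regression tree.

A CART regression tree predicts each gene's absolute prediction error
from its composition features, so its leaves collect genes with similar
composition *and* similar model accuracy.  Trees are grown with a minimum
leaf size (default 100 genes) and pruned by cost-complexity with the
penalty chosen by 10-fold cross-validation to minimize mean squared
error.  Leaves become gene groups; pooling groups across samples, the
"well predicted" ones are those whose mean error falls below the first
quartile of all group mean errors.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import KFold
from sklearn.tree import DecisionTreeRegressor

logger = logging.getLogger(__name__)


@dataclass
class GeneGroup:
    group_id: str
    genes: list[str]
    mean_abs_error: float
    split_path: list[tuple[str, float, str]] = field(default_factory=list)
    sample_id: str = ""


@dataclass
class ErrorTree:
    tree: DecisionTreeRegressor
    feature_names: list[str]
    groups: list[GeneGroup]
    ccp_alpha: float

    def to_dict(self) -> dict:
        return _dump_node(self.tree.tree_, 0, self.feature_names)


def _dump_node(t, node: int, names: list[str]) -> dict:
    if t.children_left[node] == -1:
        return {"leaf": True, "n": int(t.n_node_samples[node]), "value": float(t.value[node][0][0])}
    return {
        "leaf": False,
        "variable": names[t.feature[node]],
        "threshold": float(t.threshold[node]),
        "left": _dump_node(t, t.children_left[node], names),
        "right": _dump_node(t, t.children_right[node], names),
    }


def fit_error_tree(
    features: pd.DataFrame,
    abs_error: pd.Series,
    min_leaf: int = 100,
    seed: int = 0,
    cv_k: int = 10,
    sample_id: str = "",
) -> ErrorTree:
    """Fit and prune the error tree; leaves become :class:`GeneGroup` s."""
    common = features.index.intersection(abs_error.index)
    if len(common) < 2 * min_leaf:
        raise ValueError(f"need at least {2 * min_leaf} genes, got {len(common)}")
    X = features.loc[common].to_numpy()
    y = abs_error.loc[common].to_numpy(dtype=float)

    base = DecisionTreeRegressor(min_samples_leaf=min_leaf, random_state=seed)
    path = base.cost_complexity_pruning_path(X, y)
    alphas = np.unique(np.clip(path.ccp_alphas, 0.0, None))
    best_alpha = _select_alpha_by_cv(X, y, alphas, min_leaf, seed, cv_k)
    tree = DecisionTreeRegressor(
        min_samples_leaf=min_leaf, random_state=seed, ccp_alpha=best_alpha
    )
    tree.fit(X, y)
    groups = _leaves_to_groups(tree, X, features.columns.tolist(), list(common), y, sample_id)
    logger.info("error tree: %d leaves (ccp_alpha=%.3g)", len(groups), best_alpha)
    return ErrorTree(tree=tree, feature_names=features.columns.tolist(), groups=groups, ccp_alpha=best_alpha)


def _select_alpha_by_cv(
    X: np.ndarray, y: np.ndarray, alphas: np.ndarray, min_leaf: int, seed: int, cv_k: int
) -> float:
    if len(alphas) == 1 or len(y) < cv_k:
        return float(alphas[0])
    kf = KFold(n_splits=cv_k, shuffle=True, random_state=seed)
    mse = np.zeros(len(alphas))
    for train, test in kf.split(X):
        for i, alpha in enumerate(alphas):
            t = DecisionTreeRegressor(
                min_samples_leaf=min_leaf, random_state=seed, ccp_alpha=alpha
            )
            t.fit(X[train], y[train])
            mse[i] += ((t.predict(X[test]) - y[test]) ** 2).sum()
    mse /= len(y)
    # prefer the strongest pruning within numerical reach of the minimum
    best = mse.min()
    candidates = np.nonzero(mse <= best * (1 + 1e-10))[0]
    return float(alphas[candidates.max()])


def _leaves_to_groups(
    tree: DecisionTreeRegressor,
    X: np.ndarray,
    feature_names: list[str],
    gene_ids: list[str],
    abs_error: np.ndarray,
    sample_id: str,
) -> list[GeneGroup]:
    leaf_of_gene = tree.apply(X)
    paths = _split_paths(tree.tree_, feature_names)
    groups: list[GeneGroup] = []
    for i, leaf in enumerate(np.unique(leaf_of_gene)):
        mask = leaf_of_gene == leaf
        groups.append(
            GeneGroup(
                group_id=f"{sample_id + ':' if sample_id else ''}leaf{i}",
                genes=[gid for gid, m in zip(gene_ids, mask) if m],
                mean_abs_error=float(abs_error[mask].mean()),
                split_path=paths[int(leaf)],
                sample_id=sample_id,
            )
        )
    return groups


def _split_paths(t, names: list[str]) -> dict[int, list[tuple[str, float, str]]]:
    paths: dict[int, list[tuple[str, float, str]]] = {}

    def walk(node: int, path: list[tuple[str, float, str]]) -> None:
        if t.children_left[node] == -1:
            paths[node] = path
            return
        var, thr = names[t.feature[node]], float(t.threshold[node])
        walk(t.children_left[node], path + [(var, thr, "<=")])
        walk(t.children_right[node], path + [(var, thr, ">")])

    walk(0, [])
    return paths


def flag_well_predicted(groups: list[GeneGroup]) -> list[GeneGroup]:
    """Keep groups whose mean error is strictly below the pooled first quartile.

    The quartile is the linear-interpolation (type-7) quantile of all group
    mean errors; with identical errors nothing is flagged.
    """
    if len(groups) < 4:
        raise ValueError("need at least 4 groups to compute a quartile cut")
    errors = np.array([g.mean_abs_error for g in groups])
    cut = float(np.quantile(errors, 0.25))
    return [g for g in groups if g.mean_abs_error < cut]


def groups_to_frame(groups: list[GeneGroup], flagged: list[GeneGroup] | None = None) -> pd.DataFrame:
    flagged_ids = {id(g) for g in (flagged or [])}
    rows = [
        (g.sample_id, g.group_id, gene, g.mean_abs_error, id(g) in flagged_ids)
        for g in groups
        for gene in g.genes
    ]
    return pd.DataFrame(rows, columns=["sample", "group", "gene", "mean_abs_error", "flagged"])
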