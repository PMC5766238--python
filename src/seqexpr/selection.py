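"""Variable and region selection on top of the lasso.

* Forward region selection: region feature blocks are added greedily, one
  at a time, each step keeping the block that maximizes the
  cross-validated Spearman correlation of the cumulative model, until all
  blocks are included.
* Stability selection: the lasso is refit many times on random halves of
  the genes with independent U[0.5, 1] weights scaling each standardized
  variable; a variable is "stable" if it is selected (nonzero
  coefficient) in more than 70% of the iterations.  The random weights
  act as per-variable penalty reweighting, so correlated variables share
  selections fairly.
* Effect signs: an ordinary least-squares fit of expression on the stable
  standardized variables; the sign of each coefficient gives the
  activating (+) or inhibiting (-) direction of the variable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import _cv_mse_path, _lasso_at, evaluate_cv, lambda_grid, standardize

logger = logging.getLogger(__name__)


@dataclass
class ForwardStep:
    region: str
    cumulative_rho: float
    increment: float


@dataclass
class ForwardPath:
    steps: list[ForwardStep]

    @property
    def order(self) -> list[str]:
        return [s.region for s in self.steps]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(s.region, s.cumulative_rho, s.increment) for s in self.steps],
            columns=["region", "cumulative_rho", "increment"],
        )


@dataclass
class StabilityReport:
    frequency: pd.Series  # per variable, in [0, 1]
    threshold: float
    n_iter: int
    signs: pd.DataFrame | None = None  # per stable variable: coefficient, sign

    @property
    def stable(self) -> list[str]:
        return list(self.frequency.index[self.frequency > self.threshold])

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "frequency": self.frequency.round(3),
                "stable": self.frequency > self.threshold,
            }
        )
        if self.signs is not None:
            df = df.join(self.signs)
        return df


def forward_select_regions(
    feature_blocks: dict[str, pd.DataFrame],
    y: pd.Series,
    k: int = 10,
    seed: int = 0,
    n_alphas: int = 100,
) -> ForwardPath:
    """Greedy forward selection over region feature blocks.

    All blocks are first evaluated separately and the best becomes the
    seed region; then each remaining block is added in turn and the best
    addition kept, until every block is in the model.  Ties are broken by
    region-name lexicographic order (candidates are scanned in sorted
    order and replaced only on strict improvement).
    """
    if len(feature_blocks) < 1:
        raise ValueError("need at least one feature block")
    remaining = sorted(feature_blocks)
    chosen: list[str] = []
    steps: list[ForwardStep] = []
    prev_rho = 0.0
    while remaining:
        best_region, best_rho = None, -np.inf
        for region in remaining:
            parts = [feature_blocks[r] for r in chosen] + [feature_blocks[region]]
            X = pd.concat(parts, axis=1)
            result = evaluate_cv(X, y, k=k, seed=seed, n_alphas=n_alphas)
            if result.spearman_rho > best_rho:
                best_region, best_rho = region, result.spearman_rho
        logger.info("forward selection: + %s (rho=%.4f)", best_region, best_rho)
        steps.append(
            ForwardStep(
                region=best_region,
                cumulative_rho=best_rho,
                increment=best_rho - (prev_rho if chosen else 0.0),
            )
        )
        chosen.append(best_region)
        remaining.remove(best_region)
        prev_rho = best_rho
    return ForwardPath(steps=steps)


def stability_select(
    X: pd.DataFrame,
    y: pd.Series,
    n_iter: int = 500,
    subsample: float = 0.5,
    weight_range: tuple[float, float] = (0.5, 1.0),
    threshold: float = 0.7,
    seed: int = 0,
    cv_k: int = 5,
    n_alphas: int = 100,
    min_genes: int = 50,
) -> StabilityReport:
    """Selection frequencies of the randomized lasso over gene subsamples.

    Each iteration uses ``subsample`` of the genes (drawn uniformly without
    replacement) and scales every standardized variable by an independent
    uniform weight from ``weight_range`` before fitting the lasso at the
    iteration's own CV-selected penalty.  A variable counts as selected
    when its coefficient is nonzero.
    """
    if n_iter < 2:
        raise ValueError("n_iter must be >= 2")
    if not 0 < subsample < 1:
        raise ValueError("subsample must be in (0, 1)")
    n = len(y)
    m = int(round(n * subsample))
    if m < min_genes:
        raise ValueError(f"subsample of {m} genes is below the minimum of {min_genes}")

    Xs_df, _, _ = standardize(X)
    Xs = Xs_df.to_numpy()
    yc = y.to_numpy(dtype=float) - float(y.mean())
    rng = np.random.default_rng(seed)
    counts = np.zeros(Xs.shape[1])
    for it in range(n_iter):
        idx = rng.choice(n, size=m, replace=False)
        w = rng.uniform(*weight_range, size=Xs.shape[1])
        Xw = Xs[idx] * w
        yw = yc[idx] - yc[idx].mean()
        alphas = lambda_grid(Xw, yw, n_alphas=n_alphas)
        cv_mse = _cv_mse_path(Xw, yw, alphas, cv_k, seed=int(rng.integers(2**31)))
        lam = float(alphas[int(np.argmin(cv_mse))])
        coef = _lasso_at(Xw, yw, lam)
        counts += np.abs(coef) > 1e-10
    freq = pd.Series(counts / n_iter, index=Xs_df.columns)
    return StabilityReport(frequency=freq, threshold=threshold, n_iter=n_iter)


def effect_signs(X_stable: pd.DataFrame, y: pd.Series) -> pd.DataFrame:
    """OLS on the stable standardized variables; signs give effect direction.

    A rank-deficient (collinear) stable set falls back to the minimum-norm
    least-squares solution with a warning.
    """
    if X_stable.shape[1] == 0:
        raise ValueError("stable set is empty")
    Xs_df, _, _ = standardize(X_stable)
    Xs = Xs_df.to_numpy()
    yc = y.to_numpy(dtype=float) - float(y.mean())
    coef, _, rank, _ = np.linalg.lstsq(Xs, yc, rcond=None)
    if rank < Xs.shape[1]:
        logger.warning(
            "stable set is collinear (rank %d < %d); using minimum-norm solution",
            rank, Xs.shape[1],
        )
    return pd.DataFrame(
        {
            "coefficient": pd.Series(coef, index=Xs_df.columns),
            "sign": ["+" if c > 0 else "-" if c < 0 else "0" for c in coef],
        }
    )


def attach_signs(report: StabilityReport, X: pd.DataFrame, y: pd.Series) -> StabilityReport:
    """Fill the report's sign table from an OLS fit on its stable variables."""
    stable = report.stable
    if stable:
        report.signs = effect_signs(X[stable], y)
    else:
        report.signs = pd.DataFrame(columns=["coefficient", "sign"])
    return report
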