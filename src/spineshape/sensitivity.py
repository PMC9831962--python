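"""Shape-mode importance analysis: correlations and Kernel SHAP.

Per-mode Pearson and Spearman correlations (with two-sided p-values at a
0.05 significance level by default) diagnose the linearity of the
mode-to-outcome relationships.  Global importance uses Shapley values
estimated with the Kernel SHAP weighted-least-squares scheme on an
ordinary-least-squares linear surrogate of the outcome: coalitions are
enumerated in descending Shapley-kernel weight (extreme cardinalities
first) up to a budget, missing features are replaced by the background
weight vector, and the local-accuracy constraint is enforced exactly.
Normalised averaged absolute Shapley values give each mode's contribution
percentage; a drop-based cutoff selects the "important" mode set.

Subjects whose simulation failed screening are dropped listwise before any
of this.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import LinearRegression


@dataclass
class ShapConfig:
    """Kernel SHAP settings."""

    n_coalitions: int = 1024
    background: np.ndarray | None = None  # default: mean of the weight matrix
    surrogate: str = "linear_regression"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_coalitions < 1:
            raise ValueError("n_coalitions must be >= 1")
        if self.surrogate != "linear_regression":
            raise ValueError("only the linear_regression surrogate is supported")


def correlation_map(
    weights: np.ndarray,
    outcomes: dict | pd.DataFrame,
    significance_level: float = 0.05,
) -> pd.DataFrame:
    """Per-mode Pearson r and Spearman rho against each outcome.

    Constant columns yield NaN coefficients flagged ``undefined`` rather
    than zero (the correlation does not exist).  Spearman uses average
    ranks, which carries the standard tie correction.
    """
    weights = np.asarray(weights, dtype=float)
    if isinstance(outcomes, dict):
        outcomes = pd.DataFrame(outcomes)
    n, M = weights.shape
    if n < 4:
        raise ValueError("at least 4 subjects are required")
    if len(outcomes) != n:
        raise ValueError("outcomes and weights must have matching rows")
    rows = []
    for outcome in outcomes.columns:
        y = outcomes[outcome].to_numpy(dtype=float)
        for m in range(M):
            x = weights[:, m]
            undefined = np.ptp(x) == 0 or np.ptp(y) == 0
            if undefined:
                pr, pp, sr, sp = (np.nan,) * 4
            else:
                pr, pp = stats.pearsonr(x, y)
                sr, sp = stats.spearmanr(x, y)
            rows.append(
                {
                    "outcome": outcome,
                    "mode": m + 1,
                    "pearson_r": pr,
                    "pearson_p": pp,
                    "spearman_rho": sr,
                    "spearman_p": sp,
                    "pearson_significant": bool(pp <= significance_level)
                    if not undefined
                    else False,
                    "spearman_significant": bool(sp <= significance_level)
                    if not undefined
                    else False,
                    "undefined": undefined,
                }
            )
    return pd.DataFrame(rows)


def _shapley_kernel_weight(M: int, s: int) -> float:
    return (M - 1) / (comb(M, s) * s * (M - s))


def _enumerate_coalitions(M: int, budget: int, rng: np.random.Generator):
    """Coalition masks (without the empty/full sets) in descending kernel
    weight; cardinalities are paired (s with M-s) and filled greedily, the
    last partially-filled cardinality sampled uniformly without replacement."""
    sizes = sorted(
        range(1, M), key=lambda s: (-_shapley_kernel_weight(M, s), s)
    )
    masks = []
    remaining = budget
    for s in sizes:
        if remaining <= 0:
            break
        count = comb(M, s)
        if count <= remaining:
            for idx in combinations(range(M), s):
                mask = np.zeros(M)
                mask[list(idx)] = 1.0
                masks.append(mask)
            remaining -= count
        else:
            seen = set()
            while len(seen) < remaining:
                idx = tuple(sorted(rng.choice(M, size=s, replace=False)))
                seen.add(idx)
            for idx in sorted(seen):
                mask = np.zeros(M)
                mask[list(idx)] = 1.0
                masks.append(mask)
            remaining = 0
    return np.asarray(masks)


def kernel_shap(
    weights: np.ndarray,
    outcome: np.ndarray,
    config: ShapConfig | None = None,
) -> np.ndarray:
    """Per-subject, per-mode Shapley values of the linear surrogate.

    Fits ``f(x) = beta0 + beta . x`` by ordinary least squares, then solves
    the Shapley-kernel weighted least squares over the enumerated
    coalitions with the local-accuracy constraint
    ``sum_m phi_m(x) = f(x) - f(background)`` enforced by elimination.
    Returns an ``(n, M)`` array.
    """
    config = config or ShapConfig()
    X = np.asarray(weights, dtype=float)
    y = np.asarray(outcome, dtype=float)
    n, M = X.shape
    if n <= M:
        raise ValueError(
            f"surrogate fit needs more subjects ({n}) than modes ({M})"
        )
    if M > 1 and config.n_coalitions < M + 2:
        raise ValueError(
            f"n_coalitions={config.n_coalitions} underdetermines {M} Shapley values"
        )
    surrogate = LinearRegression().fit(X, y)
    beta = surrogate.coef_
    background = (
        X.mean(axis=0) if config.background is None
        else np.asarray(config.background, dtype=float)
    )
    f_x = surrogate.predict(X)
    f_b = float(surrogate.predict(background[None, :])[0])
    delta = f_x - f_b  # (n,)

    if M == 1:
        return delta[:, None]

    rng = np.random.default_rng(config.seed)
    Z = _enumerate_coalitions(M, config.n_coalitions, rng)  # (C, M)
    w = np.array([_shapley_kernel_weight(M, int(z.sum())) for z in Z])

    # masked surrogate value relative to the background, per subject:
    # y_cz = sum_j beta_j (x_j - b_j) z_j
    contrib = (X - background) * beta  # (n, M)
    Y = Z @ contrib.T  # (C, n)

    # eliminate phi_M through the local-accuracy constraint
    zM = Z[:, -1]
    A = Z[:, :-1] - zM[:, None]  # (C, M-1)
    B = Y - zM[:, None] * delta[None, :]  # (C, n)
    Aw = A * w[:, None]
    gram = A.T @ Aw
    try:
        solve = np.linalg.solve(gram, Aw.T @ B)  # (M-1, n)
    except np.linalg.LinAlgError as exc:
        raise ValueError(
            "coalition design is rank deficient; increase n_coalitions"
        ) from exc
    phi = np.empty((n, M))
    phi[:, :-1] = solve.T
    phi[:, -1] = delta - solve.sum(axis=0)
    return phi


def contribution_percentages(shap_values: np.ndarray) -> np.ndarray:
    """Mean |phi| per mode, normalised to sum to 100%.

    All-zero Shapley values make the contribution undefined; NaNs are
    returned (explicitly, not silently uniform).
    """
    shap_values = np.asarray(shap_values, dtype=float)
    mean_abs = np.abs(shap_values).mean(axis=0)
    total = mean_abs.sum()
    if total == 0:
        return np.full(mean_abs.shape, np.nan)
    return 100.0 * mean_abs / total


def importance_cutoff(
    percentages: np.ndarray,
    window: int = 8,
    min_relative_drop: float = 0.2,
) -> list:
    """Mode indices (0-based) before the largest relative contribution drop.

    Contributions are sorted descending; within the top-``window`` ranks the
    largest consecutive relative drop marks the cutoff.  If no drop reaches
    ``min_relative_drop`` (e.g. near-uniform contributions) the important
    set is empty.  Ties break toward the smaller set.
    """
    percentages = np.asarray(percentages, dtype=float)
    if percentages.size < 2:
        raise ValueError("at least 2 modes are required")
    order = np.argsort(-percentages, kind="stable")
    sorted_pct = percentages[order]
    limit = min(window, sorted_pct.size - 1)
    drops = np.zeros(limit)
    for i in range(limit):
        if sorted_pct[i] > 0:
            drops[i] = (sorted_pct[i] - sorted_pct[i + 1]) / sorted_pct[i]
    best = int(np.argmax(drops))
    if drops[best] < min_relative_drop:
        return []
    return order[: best + 1].tolist()


@dataclass
class SensitivityReport:
    """Bundled output of the importance analysis for all outcomes."""

    correlations: pd.DataFrame
    shap_values: dict  # outcome -> (n, M) array
    contributions: pd.DataFrame  # modes x outcomes, percentages
    ranks: pd.DataFrame  # modes x outcomes, 1 = most important
    important_sets: dict  # outcome -> list of 0-based mode indices
    significance_level: float
    n_subjects: int
    metadata: dict = field(default_factory=dict)

    def to_csv(self, path) -> None:
        self.contributions.join(self.ranks, lsuffix="_pct", rsuffix="_rank").to_csv(path)

    def to_json(self, path) -> None:
        payload = {
            "significance_level": self.significance_level,
            "n_subjects": self.n_subjects,
            "contribution_pct": {
                c: self.contributions[c].tolist() for c in self.contributions
            },
            "ranks": {c: self.ranks[c].tolist() for c in self.ranks},
            "important_modes_1based": {
                k: [m + 1 for m in v] for k, v in self.important_sets.items()
            },
            "metadata": self.metadata,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


def analyse(
    weights: np.ndarray,
    outcomes: pd.DataFrame,
    valid: np.ndarray | None = None,
    significance_level: float = 0.05,
    shap_config: ShapConfig | None = None,
) -> SensitivityReport:
    """Full importance analysis over every outcome column.

    ``valid`` (boolean per subject) drops failed simulations listwise.
    Weights are analysed in SD units if the caller provides them so; the
    metadata records whatever convention was used upstream.
    """
    weights = np.asarray(weights, dtype=float)
    if isinstance(outcomes, dict):
        outcomes = pd.DataFrame(outcomes)
    if valid is not None:
        valid = np.asarray(valid, dtype=bool)
        weights = weights[valid]
        outcomes = outcomes.loc[valid].reset_index(drop=True)
    config = shap_config or ShapConfig()
    n, M = weights.shape
    correlations = correlation_map(weights, outcomes, significance_level)
    shap_values, contribs, ranks, important = {}, {}, {}, {}
    for outcome in outcomes.columns:
        phi = kernel_shap(weights, outcomes[outcome].to_numpy(), config)
        shap_values[outcome] = phi
        pct = contribution_percentages(phi)
        contribs[outcome] = pct
        order = np.argsort(-pct, kind="stable")
        rank = np.empty(M, dtype=int)
        rank[order] = np.arange(1, M + 1)
        ranks[outcome] = rank
        important[outcome] = importance_cutoff(pct)
    index = pd.Index([f"mode_{m + 1}" for m in range(M)], name="mode")
    return SensitivityReport(
        correlations=correlations,
        shap_values=shap_values,
        contributions=pd.DataFrame(contribs, index=index),
        ranks=pd.DataFrame(ranks, index=index),
        important_sets=important,
        significance_level=significance_level,
        n_subjects=n,
        metadata={
            "n_coalitions": config.n_coalitions,
            "surrogate": config.surrogate,
            "seed": config.seed,
        },
    )


def plot_correlation_heatmap(report: SensitivityReport, path) -> None:
    """Correlation heat map with insignificant cells masked white."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = report.correlations
    outcomes = df["outcome"].unique()
    modes = sorted(df["mode"].unique())
    fig, axes = plt.subplots(
        2, 1, figsize=(max(6, len(modes) * 0.4), 4), constrained_layout=True
    )
    for ax, (stat, sig) in zip(
        axes, [("pearson_r", "pearson_significant"), ("spearman_rho", "spearman_significant")]
    ):
        grid = np.full((len(outcomes), len(modes)), np.nan)
        for i, outcome in enumerate(outcomes):
            sub = df[df["outcome"] == outcome]
            vals = np.where(sub[sig], sub[stat], np.nan)
            grid[i] = vals
        im = ax.imshow(grid, vmin=-1, vmax=1, cmap="coolwarm", aspect="auto")
        ax.set_yticks(range(len(outcomes)), outcomes)
        ax.set_xticks(range(len(modes)), modes, fontsize=7)
        ax.set_title(stat)
    fig.colorbar(im, ax=axes, shrink=0.8)
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_contributions(report: SensitivityReport, path) -> None:
    """Bar chart of contribution percentages per outcome."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = report.contributions
    fig, axes = plt.subplots(
        len(df.columns), 1, figsize=(max(6, len(df) * 0.4), 3 * len(df.columns)),
        constrained_layout=True,
    )
    axes = np.atleast_1d(axes)
    for ax, outcome in zip(axes, df.columns):
        ax.bar(range(1, len(df) + 1), df[outcome])
        ax.set_xlabel("shape mode")
        ax.set_ylabel("contribution (%)")
        ax.set_title(outcome)
    fig.savefig(path, dpi=120)
    plt.close(fig)
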