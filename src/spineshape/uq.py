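"""Bootstrap uncertainty quantification of outcome means vs sample size.

Simulation outcomes are treated as random draws from the virtual
population; the percentile bootstrap of the mean (1000 resamples of the
original size by default) quantifies how well a cohort of a given size
pins down the population mean.  The sample-size sweep subsamples the
cohort without replacement at each size before bootstrapping, mapping the
shrinkage of the 95% confidence interval as the cohort grows.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde


@dataclass
class BootstrapCurve:
    """Mean estimates and CI bounds per sample size."""

    sample_sizes: np.ndarray
    mean_estimates: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    iterations: int
    seed: int
    densities: list = field(default_factory=list)  # (grid, pdf) per size

    def __post_init__(self) -> None:
        self.sample_sizes = np.asarray(self.sample_sizes, dtype=int)
        for name in ("mean_estimates", "ci_low", "ci_high"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        if not (
            np.all(self.ci_low <= self.mean_estimates + 1e-12)
            and np.all(self.mean_estimates <= self.ci_high + 1e-12)
        ):
            raise ValueError("CI bounds must bracket the mean estimate")

    @property
    def ci_width(self) -> np.ndarray:
        return self.ci_high - self.ci_low

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_size": self.sample_sizes,
                "mean": self.mean_estimates,
                "ci_low": self.ci_low,
                "ci_high": self.ci_high,
                "ci_width": self.ci_width,
            }
        )


def bootstrap_ci(
    values,
    iterations: int = 1000,
    level: float = 0.95,
    seed: int = 0,
):
    """Percentile bootstrap CI of the mean.  Returns (mean, lo, hi)."""
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError("at least 2 values are required")
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, values.size, size=(iterations, values.size))
    means = values[idx].mean(axis=1)
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(means, [alpha, 1.0 - alpha])
    return float(values.mean()), float(lo), float(hi)


def ci_vs_sample_size(
    values,
    sizes,
    iterations: int = 1000,
    level: float = 0.95,
    seed: int = 0,
    with_densities: bool = True,
) -> BootstrapCurve:
    """Bootstrap CI of the mean at gradually increasing subsample sizes.

    Each size draws a fresh subsample without replacement, then bootstraps
    it; the optional kernel-density summaries describe the bootstrap-mean
    distribution at each size.
    """
    values = np.asarray(values, dtype=float)
    sizes = np.asarray(sorted(sizes), dtype=int)
    if sizes.max() > values.size:
        raise ValueError(
            f"requested size {sizes.max()} exceeds the {values.size} available values"
        )
    if sizes.min() < 2:
        raise ValueError("every size must be >= 2")
    rng = np.random.default_rng(seed)
    means, lows, highs, densities = [], [], [], []
    for size in sizes:
        if size == values.size:
            sub = values  # full sample: no subsampling step
        else:
            sub = values[rng.choice(values.size, size=size, replace=False)]
        idx = rng.integers(0, size, size=(iterations, size))
        boot = sub[idx].mean(axis=1)
        alpha = (1.0 - level) / 2.0
        lo, hi = np.quantile(boot, [alpha, 1.0 - alpha])
        means.append(sub.mean())
        lows.append(lo)
        highs.append(hi)
        if with_densities and np.ptp(boot) > 0:
            kde = gaussian_kde(boot)
            grid = np.linspace(boot.min(), boot.max(), 64)
            densities.append((grid, kde(grid)))
        else:
            densities.append(None)
    return BootstrapCurve(
        sample_sizes=sizes,
        mean_estimates=means,
        ci_low=lows,
        ci_high=highs,
        iterations=iterations,
        seed=seed,
        densities=densities,
    )
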