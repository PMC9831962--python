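"""PCA point-distribution shape model and its performance metrics.

A shape is the flattened vector ``[x_1..x_p, y_1..y_p, z_1..z_p]`` of its
corresponded surface points.  The model represents any shape as

    s = s_bar + sum_m w_m * phi_m,

where ``s_bar`` is the cohort mean, ``phi_m`` are orthonormal shape modes
(eigenvectors of the sample covariance, computed by thin SVD of the centred
data matrix) and ``w_m`` their weights.  Mode variances ``lambda_m`` use the
t-1 divisor.  Mode retention follows a modified Kaiser rule: keep modes
whose variance is at least ``factor * mean(lambda)`` (factor 0.7 by
default).

Performance metrics:

* accuracy — RMSE between each training shape and its M-mode reconstruction;
* specificity — RMSE from model-sampled synthetic shapes to the most
  similar training shape;
* generalisation — leave-one-out reconstruction RMSE, optionally as a curve
  over the number of retained modes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .alignment import AlignedCohort
from .geometry import CorrespondedShape


def rmse_between(a: CorrespondedShape, b: CorrespondedShape) -> float:
    """Root-mean-square of per-point Euclidean distances between two shapes."""
    if a.n_points != b.n_points:
        raise ValueError(f"point counts differ: {a.n_points} vs {b.n_points}")
    d2 = np.sum((a.points - b.points) ** 2, axis=1)
    return float(np.sqrt(d2.mean()))


def _as_matrix(cohort) -> tuple[np.ndarray, list]:
    if isinstance(cohort, AlignedCohort):
        shapes = cohort.shapes
    else:
        shapes = list(cohort)
    X = np.array([s.as_vector() for s in shapes])
    return X, shapes


@dataclass
class SsmPerformance:
    """Mean +- SD of the RMSE-based model quality metrics (mm)."""

    accuracy_mean: float
    accuracy_sd: float
    specificity_mean: float
    specificity_sd: float
    generalisation_mean: float
    generalisation_sd: float
    modes_evaluated: int
    per_mode_generalisation: np.ndarray = field(default=None)

    def to_dict(self) -> dict:
        d = {
            "modes_evaluated": self.modes_evaluated,
            "accuracy_mean_mm": self.accuracy_mean,
            "accuracy_sd_mm": self.accuracy_sd,
            "specificity_mean_mm": self.specificity_mean,
            "specificity_sd_mm": self.specificity_sd,
            "generalisation_mean_mm": self.generalisation_mean,
            "generalisation_sd_mm": self.generalisation_sd,
        }
        if self.per_mode_generalisation is not None:
            d["per_mode_generalisation_mm"] = list(
                map(float, self.per_mode_generalisation)
            )
        return d


class PointDistributionModel(BaseEstimator, TransformerMixin):
    """PCA shape model with Kaiser-rule mode retention.

    Parameters
    ----------
    n_modes:
        Number of retained modes.  ``None`` (default) applies the modified
        Kaiser rule with ``kaiser_factor``.
    kaiser_factor:
        Threshold factor on the mean eigenvalue (default 0.7).

    Fitted attributes (trailing underscore) follow sklearn conventions;
    ``modes_`` has shape ``(3p, n_total_modes_)`` with orthonormal columns
    and ``eigenvalues_`` is non-increasing.
    """

    def __init__(self, n_modes: int | None = None, kaiser_factor: float = 0.7):
        self.n_modes = n_modes
        self.kaiser_factor = kaiser_factor

    # -- fitting ----------------------------------------------------------
    def fit(self, cohort, y=None):
        X, shapes = _as_matrix(cohort)
        t = X.shape[0]
        if t < 3:
            raise ValueError(f"at least 3 shapes are required, got {t}")
        self.mean_ = X.mean(axis=0)
        Xc = X - self.mean_
        # thin SVD of the centred data matrix; eigenvalues with t-1 divisor
        U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
        n_total = min(t - 1, X.shape[1])
        s = s[:n_total]
        modes = Vt[:n_total].T
        # sign convention: largest-magnitude coordinate of each mode positive
        flip = np.sign(modes[np.abs(modes).argmax(axis=0), np.arange(n_total)])
        flip[flip == 0] = 1.0
        modes *= flip
        self.modes_ = modes
        self.eigenvalues_ = s**2 / (t - 1)
        self.lambda_total_ = float(self.eigenvalues_.sum())
        self.lambda_bar_ = float(self.eigenvalues_.mean())
        self.n_total_modes_ = n_total
        self.n_points_ = X.shape[1] // 3
        self.n_training_ = t
        if self.n_modes is not None:
            if not 1 <= self.n_modes <= n_total:
                raise ValueError(
                    f"n_modes must be in [1, {n_total}], got {self.n_modes}"
                )
            self.retained_ = int(self.n_modes)
        else:
            self.retained_ = self.retain_kaiser(self.kaiser_factor)
        return self

    def _require_fitted(self) -> None:
        if not hasattr(self, "modes_"):
            raise RuntimeError("PointDistributionModel is not fitted")

    # -- core operations --------------------------------------------------
    def kaiser_threshold(self, factor: float = 0.7) -> float:
        """Mode-variance retention threshold: factor * mean(lambda)."""
        self._require_fitted()
        if factor <= 0:
            raise ValueError("factor must be positive")
        return factor * self.lambda_bar_

    def retain_kaiser(self, factor: float = 0.7) -> int:
        """Number of modes with variance >= factor * mean(lambda)."""
        return int(np.sum(self.eigenvalues_ >= self.kaiser_threshold(factor)))

    def compactness(self, M: int) -> float:
        """Cumulative explained-variance fraction of the first M modes."""
        self._require_fitted()
        if not 1 <= M <= self.n_total_modes_:
            raise ValueError(f"M must be in [1, {self.n_total_modes_}], got {M}")
        return float(self.eigenvalues_[:M].sum() / self.lambda_total_)

    def reconstruct(self, weights: np.ndarray, subject_id: str = "") -> CorrespondedShape:
        """Shape from mode weights: mean + sum w_m phi_m (raw mm units)."""
        self._require_fitted()
        weights = np.atleast_1d(np.asarray(weights, dtype=float))
        if weights.size > self.n_total_modes_:
            raise ValueError(
                f"{weights.size} weights given but only "
                f"{self.n_total_modes_} modes are available"
            )
        vector = self.mean_ + self.modes_[:, : weights.size] @ weights
        return CorrespondedShape.from_vector(vector, subject_id)

    def project(self, shape: CorrespondedShape, M: int | None = None) -> np.ndarray:
        """Mode weights of a shape (projection onto the first M modes)."""
        self._require_fitted()
        M = self.retained_ if M is None else M
        return self.modes_[:, :M].T @ (shape.as_vector() - self.mean_)

    # -- sklearn-style surface -------------------------------------------
    def transform(self, shapes) -> np.ndarray:
        """Weights of each shape on the retained modes, as an (n, M) array."""
        self._require_fitted()
        X, _ = _as_matrix(shapes)
        return (X - self.mean_) @ self.modes_[:, : self.retained_]

    def inverse_transform(self, W: np.ndarray) -> list:
        W = np.atleast_2d(np.asarray(W, dtype=float))
        return [self.reconstruct(w, f"reconstructed_{i}") for i, w in enumerate(W)]

    def mean_shape(self) -> CorrespondedShape:
        self._require_fitted()
        return CorrespondedShape.from_vector(self.mean_, "mean")

    # -- sampling and displacement maps -----------------------------------
    def sample_weights(
        self,
        n: int,
        M: int | None = None,
        sd_range: float | None = 2.0,
        seed: int | None = None,
    ) -> np.ndarray:
        """Draw mode weights from Normal(0, lambda_m), truncated at +-sd_range SD."""
        self._require_fitted()
        M = self.retained_ if M is None else M
        rng = np.random.default_rng(seed)
        sd = np.sqrt(self.eigenvalues_[:M])
        if sd_range is None:
            z = rng.standard_normal((n, M))
        else:
            from scipy.stats import truncnorm

            z = truncnorm.rvs(-sd_range, sd_range, size=(n, M), random_state=rng)
        return z * sd

    def mode_displacement_map(self, mode: int, sd_multiple: float = 2.0) -> np.ndarray:
        """Per-point Euclidean displacement of one mode at +-k SD (mm)."""
        self._require_fitted()
        disp = (
            sd_multiple
            * np.sqrt(self.eigenvalues_[mode])
            * self.modes_[:, mode].reshape(3, -1).T
        )
        return np.linalg.norm(disp, axis=1)


def fit_ssm(cohort, n_modes: int | None = None, kaiser_factor: float = 0.7):
    """Convenience wrapper: fit a :class:`PointDistributionModel` on a cohort."""
    return PointDistributionModel(n_modes=n_modes, kaiser_factor=kaiser_factor).fit(cohort)


def evaluate(
    cohort,
    M: int | None = None,
    n_specificity_samples: int = 500,
    seed: int = 0,
    generalisation_curve: bool = True,
    truncate_specificity: float | None = 2.0,
) -> SsmPerformance:
    """Accuracy / specificity / generalisation suite on a training cohort.

    ``M`` defaults to the Kaiser-rule retention of the full-cohort model.
    Leave-one-out folds refit the model on t-1 shapes; the curve reports the
    fold-averaged RMSE against the number of modes used for reconstruction.
    """
    X, shapes = _as_matrix(cohort)
    t = X.shape[0]
    if t < 4:
        raise ValueError("at least 4 shapes are required for evaluation")
    model = PointDistributionModel().fit(shapes)
    if M is None:
        M = model.retained_
    if M > t - 2:
        raise ValueError(
            f"M={M} exceeds the leave-one-out mode capacity (t-2 = {t - 2})"
        )

    # accuracy
    acc = []
    for shape in shapes:
        w = model.project(shape, M)
        acc.append(rmse_between(shape, model.reconstruct(w)))
    acc = np.asarray(acc)

    # specificity
    W = model.sample_weights(
        n_specificity_samples, M=M, sd_range=truncate_specificity, seed=seed
    )
    spec = []
    for w in W:
        synthetic = model.reconstruct(w)
        spec.append(min(rmse_between(synthetic, s) for s in shapes))
    spec = np.asarray(spec)

    # generalisation (leave-one-out)
    max_modes = M if not generalisation_curve else min(t - 2, model.n_total_modes_)
    curves = np.zeros((t, max_modes))
    for i in range(t):
        fold = [s for j, s in enumerate(shapes) if j != i]
        sub = PointDistributionModel().fit(fold)
        left_out = shapes[i]
        w_full = sub.project(left_out, max_modes)
        for m in range(1, max_modes + 1):
            recon = sub.reconstruct(w_full[:m])
            curves[i, m - 1] = rmse_between(left_out, recon)
    gen = curves[:, min(M, max_modes) - 1]

    return SsmPerformance(
        accuracy_mean=float(acc.mean()),
        accuracy_sd=float(acc.std(ddof=1)),
        specificity_mean=float(spec.mean()),
        specificity_sd=float(spec.std(ddof=1)),
        generalisation_mean=float(gen.mean()),
        generalisation_sd=float(gen.std(ddof=1)),
        modes_evaluated=int(M),
        per_mode_generalisation=curves.mean(axis=0) if generalisation_curve else None,
    )
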