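"""Feature assembly, standardization and PCA for spectrum classification.

Impedance features are ``log10 |Z(f_i)|`` in grid order (values span
decades, so the log keeps columns comparable); the combined mode appends
the four fitted circuit parameters encoded as ``log10 R_b, log10 R_Ct,
log10 Q, alpha``. Standardization statistics are fitted on training rows
only and applied unchanged to test rows to avoid leakage. PCA components
carry a deterministic sign convention: each loading vector is flipped so
its largest-magnitude entry is positive.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.decomposition import PCA

from .exceptions import InsufficientDataError, InvalidArgumentError
from .fitting import FitResult
from .synthdata import LabeledDataset

__all__ = [
    "FeatureMatrix",
    "StandardizeStats",
    "PCAModel",
    "build_features",
    "standardize_fit",
    "standardize_apply",
    "pca_fit",
    "pca_transform",
    "PARAM_FEATURE_NAMES",
]

PARAM_FEATURE_NAMES = ("log10_r_b", "log10_r_ct", "log10_q", "alpha")


@dataclass(frozen=True)
class FeatureMatrix:
    values: np.ndarray
    feature_names: tuple
    labels: np.ndarray
    mode: str

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(v)):
            raise InvalidArgumentError("feature matrix contains non-finite entries")
        if v.shape[1] != len(self.feature_names):
            raise InvalidArgumentError("feature_names length mismatch")
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "labels", np.asarray(self.labels, dtype=float))


def build_features(
    dataset: LabeledDataset,
    fits: list[FitResult] | None = None,
    mode: str = "impedance_only",
) -> FeatureMatrix:
    """Assemble the samples x features matrix.

    ``impedance_only``: one ``log10|Z|`` column per grid frequency (60 by
    default). ``combined``: those plus the 4 circuit-parameter columns;
    requires one fit per sample.
    """
    if mode not in ("impedance_only", "combined"):
        raise InvalidArgumentError(f"unknown feature mode {mode!r}")
    imp = np.vstack([np.log10(s.spectrum.modulus) for s in dataset.samples])
    freqs = dataset.grid.frequencies
    names = [f"log10_z_mod_{f:.6g}hz" for f in freqs]
    if mode == "combined":
        if fits is None or len(fits) != len(dataset):
            raise InvalidArgumentError(
                "combined mode requires exactly one FitResult per sample"
            )
        par = np.array(
            [
                [
                    np.log10(f.params.r_b),
                    np.log10(f.params.r_ct),
                    np.log10(f.params.q),
                    f.params.alpha,
                ]
                for f in fits
            ]
        )
        values = np.hstack([imp, par])
        names += list(PARAM_FEATURE_NAMES)
    else:
        values = imp
    return FeatureMatrix(
        values=values, feature_names=tuple(names), labels=dataset.labels, mode=mode
    )


@dataclass(frozen=True)
class StandardizeStats:
    mean: np.ndarray
    sd: np.ndarray


def standardize_fit(values: np.ndarray) -> StandardizeStats:
    """Per-column mean/sd from (training) rows; zero-variance columns keep
    sd = 1 so they map to all-zero columns."""
    values = np.asarray(values, dtype=float)
    mean = values.mean(axis=0)
    sd = values.std(axis=0)
    sd = np.where(sd == 0, 1.0, sd)
    return StandardizeStats(mean=mean, sd=sd)


def standardize_apply(values: np.ndarray, stats: StandardizeStats) -> np.ndarray:
    return (np.asarray(values, dtype=float) - stats.mean) / stats.sd


@dataclass(frozen=True)
class PCAModel:
    """All-component PCA of a standardized matrix.

    ``loadings`` is (n_components, n_features) with the deterministic sign
    convention applied; ``explained_variance_ratios`` are non-negative,
    non-increasing and sum to 1; ``n_selected`` is the smallest k whose
    cumulative ratio reaches the variance threshold, floored at
    ``min_components``. ``center`` is the per-feature mean removed before
    projection.
    """

    loadings: np.ndarray
    explained_variance_ratios: np.ndarray
    n_selected: int
    center: np.ndarray


def pca_fit(
    values: np.ndarray,
    variance_threshold: float = 0.90,
    min_components: int = 1,
) -> PCAModel:
    """Principal component analysis with cumulative-variance selection.

    Components are eigenvectors of the sample covariance, ordered by
    decreasing eigenvalue (computed via sklearn's SVD-based PCA).
    """
    values = np.asarray(values, dtype=float)
    if values.shape[0] < 2:
        raise InsufficientDataError("PCA needs at least 2 rows")
    if not (0.0 < variance_threshold <= 1.0):
        raise InvalidArgumentError("variance_threshold must lie in (0, 1]")
    if min_components < 1:
        raise InvalidArgumentError("min_components must be >= 1")
    pca = PCA(svd_solver="full").fit(values)
    loadings = pca.components_.copy()
    # deterministic sign: largest-|.| entry of each loading vector positive
    for row in loadings:
        if row[np.argmax(np.abs(row))] < 0:
            row *= -1.0
    ratios = pca.explained_variance_ratio_
    cum = np.cumsum(ratios)
    k = int(np.searchsorted(cum, variance_threshold - 1e-12) + 1)
    k = min(max(k, min_components), loadings.shape[0])
    return PCAModel(
        loadings=loadings,
        explained_variance_ratios=ratios,
        n_selected=k,
        center=pca.mean_,
    )


def pca_transform(values: np.ndarray, model: PCAModel) -> np.ndarray:
    """Project rows onto the selected leading components."""
    values = np.asarray(values, dtype=float)
    return (values - model.center) @ model.loadings[: model.n_selected].T
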