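"""Per-class RGB colour statistics and the Mahalanobis colour distance.

A supervised colour classifier needs, for every canopy class (grapes, wood,
background, leaf grades), an estimate of the class's colour distribution in
RGB space: the channel means (R̄, Ḡ, B̄) and the 3x3 channel covariance
matrix S.  The Mahalanobis distance

    d(x, y) = sqrt((x - y)^T S^-1 (x - y))

then measures how far an image pixel x lies from the class representative y
in units of the class's own spread, accounting for channel correlations.
Channel order is fixed as (R, G, B) throughout the package.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

#: Epsilon used when a reference sample has literally zero colour variance.
ZERO_TRACE_EPSILON = 1e-6

#: Tolerance for the S_inv @ S == I sanity check after fitting.
INVERSE_TOL = 1e-8


class InsufficientSampleError(ValueError):
    """Raised when a pixel sample is too small for covariance estimation."""


class SingularCovarianceError(np.linalg.LinAlgError):
    """Raised when a regularized covariance still cannot be inverted."""


@dataclass(frozen=True)
class PixelSample:
    """An ordered collection of 8-bit RGB triples.

    Parameters
    ----------
    pixels : array-like of shape (n, 3)
        Integer RGB triples, each channel in [0, 255].
    """

    pixels: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.pixels, dtype=np.float64)
        if arr.ndim != 2 or arr.shape[1] != 3:
            raise ValueError(f"pixel sample must have shape (n, 3), got {arr.shape}")
        if arr.shape[0] < 1:
            raise InsufficientSampleError("insufficient sample: need at least 1 pixel")
        if arr.min() < 0 or arr.max() > 255:
            raise ValueError("pixel channel values must lie in [0, 255]")
        object.__setattr__(self, "pixels", arr)

    @property
    def n(self) -> int:
        return self.pixels.shape[0]


@dataclass(frozen=True)
class CovarianceMatrix:
    """A 3x3 RGB channel covariance with its channel means.

    ``shrinkage`` records the shrinkage weight actually applied (0 for a raw
    sample covariance).
    """

    S: np.ndarray
    means: np.ndarray
    n_source: int
    shrinkage: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "S", np.asarray(self.S, dtype=np.float64))
        object.__setattr__(self, "means", np.asarray(self.means, dtype=np.float64))


def channel_covariance(sample: PixelSample) -> CovarianceMatrix:
    """Sample covariance of the R, G, B channels with denominator n - 1.

    Raises
    ------
    InsufficientSampleError
        If the sample holds fewer than 2 pixels (the n - 1 denominator
        would vanish).
    """
    if sample.n < 2:
        raise InsufficientSampleError(
            f"insufficient sample: covariance needs n >= 2, got n={sample.n}"
        )
    means = sample.pixels.mean(axis=0)
    S = np.cov(sample.pixels.T, ddof=1)
    S = (S + S.T) / 2.0  # exact symmetry by construction
    return CovarianceMatrix(S=S, means=means, n_source=sample.n, shrinkage=0.0)


def regularize_covariance(cov: CovarianceMatrix, shrinkage: float) -> CovarianceMatrix:
    """Shrink a covariance toward a scaled identity to guarantee invertibility.

    Returns ``(1 - shrinkage) * S + shrinkage * (trace(S) / 3) * I``.  Hand
    picked reference pixels from near-uniform image regions routinely yield
    rank-deficient sample covariances; shrinkage > 0 makes the result
    positive definite.  A sample with exactly zero variance (trace 0) maps
    to ``ZERO_TRACE_EPSILON * I``.
    """
    if not 0.0 <= shrinkage <= 1.0:
        raise ValueError(f"shrinkage must lie in [0, 1], got {shrinkage}")
    tr = float(np.trace(cov.S))
    if tr == 0.0:
        S_reg = ZERO_TRACE_EPSILON * np.eye(3)
    else:
        S_reg = (1.0 - shrinkage) * cov.S + shrinkage * (tr / 3.0) * np.eye(3)
    return CovarianceMatrix(
        S=S_reg, means=cov.means, n_source=cov.n_source, shrinkage=shrinkage
    )


@dataclass(frozen=True)
class ReferenceClass:
    """A named canopy class fitted from its reference pixels.

    Holds the reference sample, the channel means, the regularized
    covariance and its inverse, the class index within a registry, and the
    class's role flags (any of ``"leaf"``, ``"grape"``, ``"background"``).
    """

    name: str
    sample: PixelSample
    means: np.ndarray
    S: CovarianceMatrix
    S_inv: np.ndarray
    index: int = 0
    roles: tuple[str, ...] = field(default=())

    def with_index(self, index: int) -> "ReferenceClass":
        return replace(self, index=index)


def fit_reference_class(
    name: str,
    sample: PixelSample,
    shrinkage: float = 0.1,
    index: int = 0,
    roles: tuple[str, ...] = (),
) -> ReferenceClass:
    """Estimate means and (regularized) inverse covariance for one class.

    Requires at least 4 reference pixels — three channels need 4 points for
    a non-degenerate sample covariance (40 per class is the conventional
    choice in field use).
    """
    if sample.n < 4:
        raise InsufficientSampleError(
            f"insufficient sample for class {name!r}: need n >= 4, got n={sample.n}"
        )
    cov = regularize_covariance(channel_covariance(sample), shrinkage)
    try:
        S_inv = np.linalg.inv(cov.S)
    except np.linalg.LinAlgError as exc:  # lam > 0 prevents this; guard anyway
        raise SingularCovarianceError(f"singular covariance for class {name!r}") from exc
    if not np.allclose(S_inv @ cov.S, np.eye(3), atol=INVERSE_TOL):
        raise SingularCovarianceError(
            f"singular covariance for class {name!r}: inverse check failed"
        )
    return ReferenceClass(
        name=name,
        sample=sample,
        means=cov.means.copy(),
        S=cov,
        S_inv=S_inv,
        index=index,
        roles=tuple(roles),
    )


def mahalanobis_distance(x, ref: ReferenceClass) -> float:
    """Distance from one RGB triple to a class centroid under the class S."""
    d = np.asarray(x, dtype=np.float64) - ref.means
    q = float(d @ ref.S_inv @ d)
    return float(np.sqrt(max(q, 0.0)))


def mahalanobis_distances(
    pixels: np.ndarray, means: np.ndarray, S_inv: np.ndarray
) -> np.ndarray:
    """Vectorized distances from an (N, 3) pixel block to one centroid."""
    d = np.asarray(pixels, dtype=np.float64) - np.asarray(means, dtype=np.float64)
    q = np.einsum("ij,jk,ik->i", d, S_inv, d)
    return np.sqrt(np.maximum(q, 0.0))
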