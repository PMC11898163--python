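"""Non-intrusive polynomial chaos expansion over standardized normal inputs.

The surrogate expresses the per-voxel acoustic intensity Y as

    Y(xi) = sum_n c_n Psi_n(xi)

where xi are the uncertain tissue properties in standard-deviation units and
Psi_n are products of probabilists' Hermite polynomials, orthonormal under
the standard normal weight (degree 0 -> 1, 1 -> xi, 2 -> (xi^2 - 1)/sqrt(2)).
Because the inputs are independent, the default truncation drops all cross
terms: the basis is the constant plus each input at each degree 1..n,
M = u*n + 1 terms (the full tensor truncation M = (u+n)!/(u!n!) is also
available). Coefficients are fitted per voxel by ordinary least squares from
black-box simulation samples; with fewer samples than terms the minimum-norm
solution is taken. Orthonormality gives closed-form moments
(mean = c_0, variance = sum_{n>=1} c_n^2).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import combinations_with_replacement
from typing import Sequence

import numpy as np

from .tissuedb import SampleSet

__all__ = [
    "PCEBasisSpec",
    "PCESurrogate",
    "basis_size",
    "build_basis",
    "fit_pce",
    "evaluate_pce",
    "pce_moments",
    "hermite_norm",
]


def basis_size(u: int, n: int, cross_terms: bool = False) -> int:
    """Number of expansion terms M.

    cross-term-free: M = u*n + 1; full tensor: M = (u+n)!/(u!*n!).
    """
    if u < 1 or n < 0:
        raise ValueError("need u >= 1 and n >= 0")
    if n == 0:
        return 1
    if cross_terms:
        return math.factorial(u + n) // (math.factorial(u) * math.factorial(n))
    return u * n + 1


@dataclass(frozen=True)
class PCEBasisSpec:
    """Multi-index basis description.

    Each multi-index is a length-u tuple of univariate degrees; the basis
    function is the product of orthonormal Hermite polynomials of those
    degrees.
    """

    u: int
    order: int
    cross_terms: bool
    indices: tuple[tuple[int, ...], ...]

    @property
    def M(self) -> int:
        return len(self.indices)


def build_basis(u: int, n: int, cross_terms: bool = False) -> PCEBasisSpec:
    """Construct the multi-index set.

    Cross-term-free: {0} plus input i at degree d for 1 <= d <= n. Full
    tensor: all multi-indices of total degree <= n.
    """
    M = basis_size(u, n, cross_terms)
    indices: list[tuple[int, ...]] = [tuple([0] * u)]
    if cross_terms:
        if n > 2:
            warnings.warn(
                "full-tensor basis with order > 2 is experimental", stacklevel=2
            )
        for total in range(1, n + 1):
            for combo in combinations_with_replacement(range(u), total):
                mi = [0] * u
                for i in combo:
                    mi[i] += 1
                indices.append(tuple(mi))
        indices.sort(key=lambda mi: (sum(mi), mi))
    else:
        for d in range(1, n + 1):
            for i in range(u):
                mi = [0] * u
                mi[i] = d
                indices.append(tuple(mi))
    assert len(indices) == M
    return PCEBasisSpec(u, n, cross_terms, tuple(indices))


def hermite_norm(degree: int, x: np.ndarray) -> np.ndarray:
    """Orthonormal probabilists' Hermite polynomial He_d(x)/sqrt(d!)."""
    x = np.asarray(x, dtype=float)
    h_prev = np.ones_like(x)
    if degree == 0:
        return h_prev
    h = x.copy()
    for d in range(1, degree):
        h, h_prev = x * h - d * h_prev, h
    return h / math.sqrt(math.factorial(degree))


def design_matrix(basis: PCEBasisSpec, xi: np.ndarray) -> np.ndarray:
    """Evaluate every basis function at each standardized input row."""
    xi = np.atleast_2d(np.asarray(xi, dtype=float))
    if xi.shape[1] != basis.u:
        raise ValueError(f"expected {basis.u} inputs per row, got {xi.shape[1]}")
    max_deg = max(max(mi) for mi in basis.indices)
    uni = np.stack(
        [hermite_norm(d, xi) for d in range(max_deg + 1)], axis=0
    )  # (deg, n, u)
    cols = []
    for mi in basis.indices:
        col = np.ones(xi.shape[0])
        for j, d in enumerate(mi):
            if d:
                col = col * uni[d, :, j]
        cols.append(col)
    return np.column_stack(cols)


@dataclass
class PCESurrogate:
    """Fitted per-voxel expansion.

    ``coeffs`` is (M, n_voxels); ``mask`` (or None for the full grid) maps
    fitted voxels back onto ``grid_shape``. ``means``/``stds`` record the
    input standardization matching ``property_index``.
    """

    basis: PCEBasisSpec
    coeffs: np.ndarray
    grid_shape: tuple[int, ...]
    mask: np.ndarray | None
    means: np.ndarray
    stds: np.ndarray
    property_index: tuple[tuple[str, str], ...]
    residual_norm: np.ndarray
    n_training: int

    @property
    def n_voxels(self) -> int:
        return self.coeffs.shape[1]

    def standardize(self, values: np.ndarray) -> np.ndarray:
        """Raw property values -> sigma units (std = 0 columns -> 0)."""
        values = np.atleast_2d(np.asarray(values, dtype=float))
        with np.errstate(invalid="ignore", divide="ignore"):
            z = (values - self.means) / self.stds
        z[:, self.stds == 0] = 0.0
        return z

    def to_grid(self, flat: np.ndarray) -> np.ndarray:
        """Scatter per-voxel values back onto the full grid (0 outside mask)."""
        if self.mask is None:
            return flat.reshape(self.grid_shape)
        out = np.zeros(self.grid_shape, dtype=flat.dtype)
        out[self.mask] = flat
        return out


def _flatten_responses(
    responses: np.ndarray, n_samples: int, mask: np.ndarray | None
) -> tuple[np.ndarray, tuple[int, ...]]:
    responses = np.asarray(responses, dtype=float)
    if responses.shape[0] != n_samples:
        raise ValueError("responses must have one row per sample")
    grid_shape = responses.shape[1:]
    flat = responses.reshape(n_samples, -1)
    if mask is not None:
        if mask.shape != grid_shape:
            raise ValueError("voxel mask shape mismatch")
        flat = flat[:, mask.reshape(-1)]
    return flat, grid_shape


def fit_pce(
    samples: SampleSet,
    responses: np.ndarray,
    basis: PCEBasisSpec,
    voxel_mask: np.ndarray | None = None,
) -> PCESurrogate:
    """Per-voxel least-squares fit of the expansion coefficients.

    ``responses`` holds one simulated intensity field per sample row
    (shape (n_samples, *grid) or (n_samples, n_voxels)). With
    n_samples < M the problem is under-determined and the minimum-norm
    solution is returned; a rank-deficient design with n_samples >= M
    (duplicated sample points) triggers a warning.
    """
    if samples.u != basis.u:
        raise ValueError(
            f"sample set has {samples.u} inputs but basis expects {basis.u}"
        )
    y, grid_shape = _flatten_responses(responses, samples.n_samples, voxel_mask)
    phi = design_matrix(basis, samples.standardized)
    coeffs, _, rank, _ = np.linalg.lstsq(phi, y, rcond=None)
    if samples.n_samples >= basis.M and rank < basis.M:
        warnings.warn(
            "rank-deficient design (duplicated sample points?); "
            "minimum-norm solution returned",
            stacklevel=2,
        )
    resid = np.linalg.norm(y - phi @ coeffs, axis=0)
    return PCESurrogate(
        basis=basis,
        coeffs=coeffs,
        grid_shape=grid_shape,
        mask=voxel_mask,
        means=samples.means.copy(),
        stds=samples.stds.copy(),
        property_index=samples.index,
        residual_norm=resid,
        n_training=samples.n_samples,
    )


def evaluate_pce(
    surrogate: PCESurrogate,
    xi: np.ndarray,
    clamp_counter: list | None = None,
) -> np.ndarray:
    """Evaluate the surrogate at standardized inputs.

    ``xi`` is one vector of length u or a batch (n, u); returns
    (n_voxels,) or (n, n_voxels). Negative predictions (possible for a
    quadratic fit of a non-negative quantity) are clamped to zero; the
    number of clamped values is appended to ``clamp_counter`` if given.
    """
    xi = np.asarray(xi, dtype=float)
    single = xi.ndim == 1
    phi = design_matrix(surrogate.basis, np.atleast_2d(xi))
    y = phi @ surrogate.coeffs
    n_neg = int((y < 0).sum())
    if clamp_counter is not None:
        clamp_counter.append(n_neg)
    np.maximum(y, 0.0, out=y)
    return y[0] if single else y


def pce_moments(surrogate: PCESurrogate):
    """Closed-form mean/std fields from the orthonormal expansion.

    mean = c_0 and variance = sum of squared non-constant coefficients,
    exact for the (orthonormal) basis used here; an alternative to the
    resampling route in :mod:`sonouq.montecarlo`.
    """
    from .montecarlo import UQField  # local import to avoid a cycle

    mean = surrogate.to_grid(surrogate.coeffs[0].copy())
    var = surrogate.to_grid(np.einsum("mv,mv->v", surrogate.coeffs[1:],
                                      surrogate.coeffs[1:]))
    return UQField(
        mean=mean,
        std=np.sqrt(var),
        n_samples=surrogate.n_training,
        source="pce-analytic",
        seed=None,
    )
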