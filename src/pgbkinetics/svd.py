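"""SVD analysis of time-resolved difference spectra.

A wavelength-by-delay matrix of difference absorbances is factored as
``M = U S V^T``; columns of U are spectral components, columns of V their
amplitude time courses.  Meaningful components are those with a large
singular value and smooth (high lag-1 autocorrelation) spectral and
amplitude vectors.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import InvalidParameterError

#: Default relative singular-value cutoff for component selection.
DEFAULT_SV_RATIO_MIN = 0.01
#: Default lag-1 autocorrelation cutoff for component selection.
DEFAULT_AUTOCORR_MIN = 0.8


@dataclass
class SpectraMatrix:
    """Difference-absorbance data on a wavelength x delay grid."""

    wavelengths: np.ndarray
    delay_times: np.ndarray
    values: np.ndarray

    def __post_init__(self):
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.delay_times = np.asarray(self.delay_times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.wavelengths.size, self.delay_times.size):
            raise InvalidParameterError(
                f"values shape {self.values.shape} does not match grids "
                f"({self.wavelengths.size} wavelengths x {self.delay_times.size} delays)"
            )
        for name, grid in (("wavelengths", self.wavelengths), ("delay_times", self.delay_times)):
            if grid.size > 1 and not np.all(np.diff(grid) > 0):
                raise InvalidParameterError(f"{name} must be strictly increasing")
        if not np.all(np.isfinite(self.values)):
            raise InvalidParameterError("spectra matrix contains non-finite entries")


def lag1_autocorrelation(v: np.ndarray) -> float:
    """Lag-1 autocorrelation sum_j v_j v_{j+1} of a unit-normalized vector."""
    v = np.asarray(v, dtype=float)
    norm = np.linalg.norm(v)
    if norm == 0 or v.size < 2:
        return 0.0
    u = v / norm
    return float(np.dot(u[:-1], u[1:]))


@dataclass
class SVDResult:
    """Decomposition of a :class:`SpectraMatrix`.

    ``spectral`` (wavelengths x k) and ``amplitudes`` (delays x k) hold
    unit-norm component columns; ``singular_values`` are sorted descending.
    The SVD sign ambiguity is resolved by making the largest-magnitude element
    of each spectral component positive.
    """

    singular_values: np.ndarray
    spectral: np.ndarray
    amplitudes: np.ndarray
    wavelengths: np.ndarray
    delay_times: np.ndarray
    autocorr_spectral: np.ndarray = field(init=False)
    autocorr_amplitude: np.ndarray = field(init=False)
    selected: np.ndarray = field(init=False)

    def __post_init__(self):
        self.autocorr_spectral = np.array(
            [lag1_autocorrelation(col) for col in self.spectral.T]
        )
        self.autocorr_amplitude = np.array(
            [lag1_autocorrelation(col) for col in self.amplitudes.T]
        )
        self.selected = select_components(self)

    @property
    def rank(self) -> int:
        """Number of singular values above a relative floor of 1e-12."""
        if self.singular_values.size == 0 or self.singular_values[0] == 0:
            return 0
        return int(np.sum(self.singular_values > 1e-12 * self.singular_values[0]))


def svd_decompose(m: SpectraMatrix) -> SVDResult:
    """Exact singular value decomposition of a spectra matrix."""
    if m.values.shape[0] < 2 or m.values.shape[1] < 2:
        raise InvalidParameterError("spectra matrix must be at least 2 x 2")
    u, s, vt = np.linalg.svd(m.values, full_matrices=False)
    v = vt.T
    # Sign convention: largest-magnitude element of each spectral column positive.
    for i in range(s.size):
        j = int(np.argmax(np.abs(u[:, i])))
        if u[j, i] < 0:
            u[:, i] = -u[:, i]
            v[:, i] = -v[:, i]
    return SVDResult(
        singular_values=s,
        spectral=u,
        amplitudes=v,
        wavelengths=m.wavelengths,
        delay_times=m.delay_times,
    )


def select_components(
    r: SVDResult,
    sv_ratio_min: float = DEFAULT_SV_RATIO_MIN,
    autocorr_min: float = DEFAULT_AUTOCORR_MIN,
) -> np.ndarray:
    """Indices (0-based) of the meaningful components.

    A component is kept iff its singular value is at least ``sv_ratio_min``
    of the largest one AND both its spectral and amplitude vectors have lag-1
    autocorrelation at least ``autocorr_min`` — i.e. it carries weight and is
    smooth in both dimensions, which white noise is not.  May select none.
    """
    for name, thr in (("sv_ratio_min", sv_ratio_min), ("autocorr_min", autocorr_min)):
        if not 0 < thr <= 1:
            raise InvalidParameterError(f"{name} must be in (0, 1], got {thr!r}")
    s = r.singular_values
    if s.size == 0 or s[0] == 0:
        return np.array([], dtype=int)
    keep = (
        (s / s[0] >= sv_ratio_min)
        & (r.autocorr_spectral >= autocorr_min)
        & (r.autocorr_amplitude >= autocorr_min)
    )
    return np.flatnonzero(keep)


def reconstruct(r: SVDResult, k: int) -> SpectraMatrix:
    """Rank-``k`` approximation of the decomposed matrix.

    By the Eckart-Young theorem this is the optimal rank-k approximation in
    the Frobenius norm, with error ``sqrt(sum of the discarded s_i^2)``.
    """
    if not 1 <= k <= r.singular_values.size:
        raise InvalidParameterError(
            f"k must be in [1, {r.singular_values.size}], got {k!r}"
        )
    values = (r.spectral[:, :k] * r.singular_values[:k]) @ r.amplitudes[:, :k].T
    return SpectraMatrix(
        wavelengths=r.wavelengths, delay_times=r.delay_times, values=values
    )
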