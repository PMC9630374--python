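"""Depolarization observables from per-pixel Mueller matrices.

A Mueller matrix M describes how a sample transforms Stokes vectors.  Its
block form

    M = m00 * [[1, D^T], [P, m]]

exposes the unpolarized transmittance/reflectance m00, the diattenuation
vector D (first row), the polarizance vector P (first column) and a 3x3
submatrix m that entangles retardance and depolarization.  From these we
compute two complementary triplets of depolarization metrics:

* the Components of Purity (CPs): diattenuation D, polarizance P and the
  degree of spherical purity P_S = ||m/m00||_F / sqrt(3);
* the Indices of Polarimetric Purity (IPPs) P1 <= P2 <= P3, linear
  combinations of the sorted, trace-normalized eigenvalues of the Cloude
  covariance matrix H(M).

Both triplets are tied together through the depolarization index

    P_Delta = sqrt(D^2 + P^2 + 3 P_S^2) / sqrt(3)
            = sqrt(2 P1^2 + (2/3) P2^2 + (1/3) P3^2) / sqrt(3),

which is 1 for a non-depolarizing (pure) element and 0 for the ideal
depolarizer diag(1,0,0,0).  The equality of the two forms is used as an
internal consistency check.

All operations are vectorized over arbitrary leading axes, so a single 4x4
matrix and an (H, W, 4, 4) image go through the same code path.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "MuellerImage",
    "CovarianceSpectrum",
    "ObservableStack",
    "CHANNEL_NAMES",
    "build_covariance",
    "eigen_spectrum",
    "ipps",
    "cps",
    "depolarization_index",
    "depolarization_index_ipp",
    "compute_observables",
]

#: Channel order used throughout file I/O and the observable stack.
CHANNEL_NAMES = ("m00", "D", "P", "P_S", "P1", "P2", "P3", "P_Delta")

#: Default clamp tolerance for small negative covariance eigenvalues,
#: relative to the covariance trace (= m00).
CLAMP_EPS = 1e-8

# Pauli basis in the conventional order: identity, sigma_z, sigma_x, sigma_y.
_SIGMA = np.array(
    [
        [[1, 0], [0, 1]],
        [[1, 0], [0, -1]],
        [[0, 1], [1, 0]],
        [[0, -1j], [1j, 0]],
    ],
    dtype=complex,
)

# _PI[a, b] = sigma_a (x) conj(sigma_b); contracting m_ab against it yields
# the Cloude covariance matrix.
_PI = np.empty((4, 4, 4, 4), dtype=complex)
for _a in range(4):
    for _b in range(4):
        _PI[_a, _b] = np.kron(_SIGMA[_a], _SIGMA[_b].conj())


class RealizabilityWarning(UserWarning):
    """A pixel's Mueller matrix is not physically realizable beyond noise tolerance."""


@dataclass
class MuellerImage:
    """Per-pixel 4x4 real Mueller matrices on an H x W raster.

    Raster convention: row-major, 0-based indices, origin top-left.
    Pixels with m00 == 0 carry no light and are masked invalid; they render
    black downstream.
    """

    elements: np.ndarray  # (H, W, 4, 4) float
    mask: np.ndarray = field(default=None)  # (H, W) bool, True = valid

    def __post_init__(self) -> None:
        self.elements = np.asarray(self.elements, dtype=float)
        if self.elements.ndim != 4 or self.elements.shape[-2:] != (4, 4):
            raise ValueError(
                f"expected elements of shape (H, W, 4, 4), got {self.elements.shape}"
            )
        if not np.all(np.isfinite(self.elements)):
            raise ValueError("Mueller elements must be finite")
        m00 = self.elements[..., 0, 0]
        if np.any(m00 < 0):
            raise ValueError("m00 must be non-negative at every pixel")
        valid = m00 > 0
        if self.mask is None:
            self.mask = valid
        else:
            self.mask = np.asarray(self.mask, dtype=bool) & valid

    @property
    def height(self) -> int:
        return self.elements.shape[0]

    @property
    def width(self) -> int:
        return self.elements.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.elements.shape[:2]


@dataclass
class CovarianceSpectrum:
    """Eigenvalues of the per-pixel Cloude covariance matrix.

    ``lambda_raw`` are the descending-sorted eigenvalues after clamping small
    negatives (same units as m00); ``lambda_hat`` are normalized by their sum.
    ``valid`` marks pixels with positive trace; ``physical`` marks pixels
    whose most negative raw eigenvalue stayed within the clamp tolerance.
    """

    lambda_raw: np.ndarray  # (..., 4) descending
    lambda_hat: np.ndarray  # (..., 4) descending, sums to 1 on valid pixels
    valid: np.ndarray  # (...,) bool
    physical: np.ndarray  # (...,) bool


@dataclass
class ObservableStack:
    """Named per-pixel depolarization channels derived from a Mueller image.

    Channels: m00 (intensity, >= 0) plus the dimensionless D, P, P_S, P1,
    P2, P3 and P_Delta, all in [0, 1] at valid physical pixels.
    """

    m00: np.ndarray
    D: np.ndarray
    P: np.ndarray
    P_S: np.ndarray
    P1: np.ndarray
    P2: np.ndarray
    P3: np.ndarray
    P_Delta: np.ndarray
    mask: np.ndarray  # True = valid pixel
    physical: np.ndarray = field(default=None)  # realizability flag

    def __post_init__(self) -> None:
        if self.physical is None:
            self.physical = np.ones_like(self.mask, dtype=bool)

    def channel(self, name: str) -> np.ndarray:
        if name not in CHANNEL_NAMES:
            raise KeyError(f"unknown channel {name!r}; expected one of {CHANNEL_NAMES}")
        return getattr(self, name)

    def triplet(self, basis: str) -> np.ndarray:
        """Stack the observable triplet for a basis: 'ipp' -> (P1, P2, P3),
        'cp' -> (P, D, P_S).  Shape (..., 3)."""
        if basis == "ipp":
            return np.stack([self.P1, self.P2, self.P3], axis=-1)
        if basis == "cp":
            return np.stack([self.P, self.D, self.P_S], axis=-1)
        raise ValueError(f"unknown observable basis {basis!r}; expected 'ipp' or 'cp'")

    def to_array(self) -> np.ndarray:
        """All channels as a (8, H, W) array in CHANNEL_NAMES order."""
        return np.stack([self.channel(n) for n in CHANNEL_NAMES], axis=0)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.m00.shape


def build_covariance(matrix: np.ndarray) -> np.ndarray:
    """Cloude covariance matrix H(M) = (1/4) sum_ab m_ab sigma_a (x) conj(sigma_b).

    Accepts a single 4x4 real matrix or any (..., 4, 4) stack.  H is Hermitian
    with trace equal to m00; for a physically realizable M it is
    positive-semidefinite, and its eigenvalues are the convex weights of the
    Cloude decomposition into four pure Mueller matrices.
    """
    matrix = np.asarray(matrix, dtype=float)
    if matrix.shape[-2:] != (4, 4):
        raise ValueError(f"expected (..., 4, 4) input, got shape {matrix.shape}")
    if not np.all(np.isfinite(matrix)):
        raise ValueError("Mueller matrix must be finite")
    return 0.25 * np.einsum("...ab,abjk->...jk", matrix, _PI)


def eigen_spectrum(H: np.ndarray, clamp_eps: float = CLAMP_EPS) -> CovarianceSpectrum:
    """Sorted, clamped, trace-normalized eigen-spectrum of H(M).

    Eigenvalues are sorted descending.  Values in [-eps, 0) with
    eps = clamp_eps * trace are treated as measurement noise and clamped to
    zero; more negative values flag the pixel as non-physical (clamped too,
    with a RealizabilityWarning).  Pixels with non-positive trace are invalid.
    """
    H = np.asarray(H)
    herm_err = np.max(np.abs(H - np.swapaxes(H, -1, -2).conj()))
    if herm_err > 1e-8 * max(1.0, float(np.max(np.abs(H)))):
        raise ValueError("covariance matrix is not Hermitian within tolerance")
    lam = np.linalg.eigvalsh(H)[..., ::-1]  # descending, real
    trace = lam.sum(axis=-1)
    valid = trace > 0
    eps = clamp_eps * np.abs(trace)
    physical = lam[..., -1] >= -eps
    n_bad = int(np.sum(~physical & valid))
    if n_bad:
        warnings.warn(
            f"{n_bad} pixel(s) have covariance eigenvalues below the noise "
            "tolerance; matrices are not physically realizable",
            RealizabilityWarning,
            stacklevel=2,
        )
    lam = np.clip(lam, 0.0, None)
    total = lam.sum(axis=-1)
    with np.errstate(divide="ignore", invalid="ignore"):
        lam_hat = np.where(valid[..., None] & (total[..., None] > 0),
                           lam / np.where(total == 0, 1.0, total)[..., None],
                           0.0)
    return CovarianceSpectrum(lambda_raw=lam, lambda_hat=lam_hat,
                              valid=valid & (total > 0), physical=physical)


def ipps(spectrum: CovarianceSpectrum) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Indices of Polarimetric Purity from a normalized eigen-spectrum.

    P1 = l0 - l1, P2 = l0 + l1 - 2 l2, P3 = l0 + l1 + l2 - 3 l3 with the
    normalized eigenvalues l0 >= l1 >= l2 >= l3; 0 <= P1 <= P2 <= P3 <= 1.
    """
    lh = spectrum.lambda_hat
    if np.any(np.diff(lh, axis=-1) > 1e-12):
        raise ValueError("spectrum must be sorted descending")
    sums = lh.sum(axis=-1)
    if np.any(np.abs(sums[spectrum.valid] - 1.0) > 1e-10):
        raise ValueError("spectrum must be normalized to unit sum on valid pixels")
    l0, l1, l2, l3 = (lh[..., i] for i in range(4))
    return l0 - l1, l0 + l1 - 2 * l2, l0 + l1 + l2 - 3 * l3


def cps(matrix: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Components of Purity (D, P, P_S) of a Mueller matrix.

    All three are computed on the m00-normalized matrix: diattenuation D from
    the first row, polarizance P from the first column, and the degree of
    spherical purity P_S as the Frobenius norm of the 3x3 submatrix divided
    by sqrt(3).  Requires m00 > 0; returns NaN where m00 == 0.
    """
    matrix = np.asarray(matrix, dtype=float)
    m00 = matrix[..., 0, 0]
    with np.errstate(divide="ignore", invalid="ignore"):
        inv = np.where(m00 > 0, 1.0 / np.where(m00 == 0, 1.0, m00), np.nan)
    D = np.sqrt(np.sum(matrix[..., 0, 1:] ** 2, axis=-1)) * inv
    P = np.sqrt(np.sum(matrix[..., 1:, 0] ** 2, axis=-1)) * inv
    P_S = np.sqrt(np.sum(matrix[..., 1:, 1:] ** 2, axis=(-2, -1))) * inv / np.sqrt(3.0)
    return D, P, P_S


def depolarization_index(D: np.ndarray, P: np.ndarray, P_S: np.ndarray) -> np.ndarray:
    """Depolarization index from the Components of Purity."""
    return np.sqrt((np.asarray(D) ** 2 + np.asarray(P) ** 2 + 3 * np.asarray(P_S) ** 2) / 3.0)


def depolarization_index_ipp(P1: np.ndarray, P2: np.ndarray, P3: np.ndarray) -> np.ndarray:
    """Depolarization index from the Indices of Polarimetric Purity."""
    return np.sqrt(
        (2 * np.asarray(P1) ** 2 + (2.0 / 3.0) * np.asarray(P2) ** 2
         + (1.0 / 3.0) * np.asarray(P3) ** 2) / 3.0
    )


def compute_observables(
    image: MuellerImage,
    clamp_eps: float = CLAMP_EPS,
    consistency_tol: float = 1e-6,
) -> ObservableStack:
    """Full per-pixel observable stack of a Mueller image.

    Runs covariance construction, eigen-decomposition and the IPPs alongside
    the CPs and the depolarization index.  Invalid pixels (m00 == 0, zero
    covariance trace) propagate as masked, with all channels set to 0 there.
    On physically realizable pixels the two closed forms of the
    depolarization index must agree; a discrepancy beyond ``consistency_tol``
    raises a RealizabilityWarning since it indicates numerical or
    realizability trouble.
    """
    H = build_covariance(image.elements)
    spec = eigen_spectrum(H, clamp_eps=clamp_eps)
    P1, P2, P3 = ipps(spec)
    D, P, P_S = cps(image.elements)
    pdelta_cp = depolarization_index(D, P, P_S)
    pdelta_ipp = depolarization_index_ipp(P1, P2, P3)

    mask = image.mask & spec.valid
    check = mask & spec.physical
    if np.any(check):
        gap = np.max(np.abs(pdelta_cp[check] - pdelta_ipp[check]))
        if gap > consistency_tol:
            warnings.warn(
                f"CP and IPP forms of the depolarization index disagree by {gap:.3e}",
                RealizabilityWarning,
                stacklevel=2,
            )

    def _clean(ch: np.ndarray) -> np.ndarray:
        out = np.where(mask, ch, 0.0)
        return np.nan_to_num(out, nan=0.0)

    return ObservableStack(
        m00=np.where(mask, image.elements[..., 0, 0], 0.0),
        D=_clean(D),
        P=_clean(P),
        P_S=_clean(P_S),
        P1=_clean(P1),
        P2=_clean(P2),
        P3=_clean(P3),
        P_Delta=_clean(pdelta_cp),
        mask=mask,
        physical=spec.physical,
    )
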