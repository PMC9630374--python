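"""Synthetic Mueller-matrix scenes with known class labels.

Real polarimetric tissue images are rarely shareable, so test scenes are
built from first principles instead: every class matrix is a convex (Cloude)
mixture of non-depolarizing pure elements

    M = m00 * sum_i w_i M_i,   w_i >= 0,  sum w_i = 1,

which is physically realizable by construction, and scenes are
piecewise-constant label maps filled with those matrices plus element-wise
additive Gaussian noise scaled by m00 (a simple stand-in for detector
noise).  Noisy matrices may be slightly non-physical; that is intentional
and exercises the eigenvalue-clamping path downstream.

Pure elements come from Jones matrices (retarders, diattenuators,
rotations), so their covariance spectrum is (1, 0, 0, 0) exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .observables import MuellerImage, build_covariance, eigen_spectrum

__all__ = [
    "PureComponentSet",
    "SyntheticScene",
    "jones_to_mueller",
    "identity_element",
    "rotation_mueller",
    "linear_retarder",
    "linear_diattenuator",
    "isotropic_depolarizer",
    "pauli_eigenstate_components",
    "is_nondepolarizing",
    "cloude_mixture",
    "random_pure_mueller",
    "random_cloude_mixture",
    "half_plane_labels",
    "stripe_labels",
    "disk_labels",
    "generate_scene",
]

# Stokes <-> Jones coherency change of basis: M = _A (J x J*) _A^{-1}.
_A = np.array(
    [
        [1, 0, 0, 1],
        [1, 0, 0, -1],
        [0, 1, 1, 0],
        [0, 1j, -1j, 0],
    ],
    dtype=complex,
)
_A_INV = np.linalg.inv(_A)


@dataclass
class PureComponentSet:
    """Convex weights and the four non-depolarizing components they mix."""

    weights: np.ndarray  # (4,) convex coefficients
    components: np.ndarray  # (4, 4, 4) pure Mueller matrices

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        self.components = np.asarray(self.components, dtype=float)
        if self.weights.shape != (4,) or self.components.shape != (4, 4, 4):
            raise ValueError("expected 4 weights and 4 pure 4x4 components")
        if np.any(self.weights < -1e-12) or abs(self.weights.sum() - 1.0) > 1e-9:
            raise ValueError("weights must be convex: non-negative and summing to 1")
        for k, comp in enumerate(self.components):
            if not is_nondepolarizing(comp):
                raise ValueError(f"component {k} is not a pure (non-depolarizing) matrix")


@dataclass
class SyntheticScene:
    """Ground truth of a generated scene."""

    label_map: np.ndarray  # (H, W) int class index
    class_matrices: np.ndarray  # (k, 4, 4) noiseless per-class Mueller matrices
    noise_sd: float
    seed: int | None


def jones_to_mueller(J: np.ndarray) -> np.ndarray:
    """Mueller matrix of a deterministic (non-depolarizing) Jones element.

    Vectorized over leading axes of a (..., 2, 2) complex stack.
    """
    J = np.asarray(J, dtype=complex)
    if J.shape[-2:] != (2, 2):
        raise ValueError(f"expected (..., 2, 2) Jones matrices, got {J.shape}")
    # J x J* as a (..., 4, 4) Kronecker product
    kron = np.einsum("...ij,...kl->...ikjl", J, J.conj()).reshape(J.shape[:-2] + (4, 4))
    M = np.einsum("ab,...bc,cd->...ad", _A, kron, _A_INV)
    return M.real


def identity_element() -> np.ndarray:
    """The neutral (free-space) element: 4x4 identity."""
    return np.eye(4)


def rotation_mueller(theta: float) -> np.ndarray:
    """Stokes rotation by physical angle theta (acts as 2*theta on s1, s2)."""
    c, s = np.cos(2 * theta), np.sin(2 * theta)
    return np.array(
        [
            [1, 0, 0, 0],
            [0, c, -s, 0],
            [0, s, c, 0],
            [0, 0, 0, 1],
        ],
        dtype=float,
    )

def _rotated(M: np.ndarray, theta: float) -> np.ndarray:
    return rotation_mueller(theta) @ M @ rotation_mueller(-theta)


def linear_retarder(delta: float, theta: float = 0.0) -> np.ndarray:
    """Linear retarder with retardance delta at fast-axis angle theta.

    delta in [0, 2*pi), theta in [0, pi).  Pure element: D = P = 0, and the
    3x3 submatrix is a rotation, so P_S = 1.
    """
    if not 0 <= delta < 2 * np.pi:
        raise ValueError(f"retardance must be in [0, 2*pi), got {delta}")
    if not 0 <= theta < np.pi:
        raise ValueError(f"axis angle must be in [0, pi), got {theta}")
    cd, sd = np.cos(delta), np.sin(delta)
    M = np.array(
        [
            [1, 0, 0, 0],
            [0, 1, 0, 0],
            [0, 0, cd, sd],
            [0, 0, -sd, cd],
        ],
        dtype=float,
    )
    return _rotated(M, theta)


def linear_diattenuator(d: float, theta: float = 0.0) -> np.ndarray:
    """Linear diattenuator with diattenuation d at axis angle theta, m00 = 1.

    d in [0, 1]; d = 1 is the ideal linear polarizer (D = P = 1).
    """
    if not 0 <= d <= 1:
        raise ValueError(f"diattenuation must be in [0, 1], got {d}")
    if not 0 <= theta < np.pi:
        raise ValueError(f"axis angle must be in [0, pi), got {theta}")
    t = np.sqrt(max(1.0 - d * d, 0.0))
    M = np.array(
        [
            [1, d, 0, 0],
            [d, 1, 0, 0],
            [0, 0, t, 0],
            [0, 0, 0, t],
        ],
        dtype=float,
    )
    return _rotated(M, theta)


def isotropic_depolarizer(a: float) -> np.ndarray:
    """Diagonal depolarizer diag(1, a, a, a); a = 0 is the ideal depolarizer.

    Its IPPs, P_S and depolarization index all equal a — a convenient
    one-parameter family for ground truth.  Not a pure element for a < 1.
    """
    if not 0 <= a <= 1:
        raise ValueError(f"depolarizer parameter must be in [0, 1], got {a}")
    return np.diag([1.0, a, a, a])


def pauli_eigenstate_components() -> np.ndarray:
    """The four pure components whose Jones matrices are the Pauli basis.

    Their equal-weight mixture is the ideal depolarizer diag(1, 0, 0, 0).
    """
    sigma = np.array(
        [
            [[1, 0], [0, 1]],
            [[1, 0], [0, -1]],
            [[0, 1], [1, 0]],
            [[0, -1j], [1j, 0]],
        ],
        dtype=complex,
    )
    return jones_to_mueller(sigma)


def is_nondepolarizing(M: np.ndarray, tol: float = 1e-8) -> bool:
    """True when M's covariance spectrum is (1, 0, 0, 0) within tol."""
    spec = eigen_spectrum(build_covariance(M))
    if not bool(np.all(spec.valid)):
        return False
    target = np.array([1.0, 0.0, 0.0, 0.0])
    return bool(np.all(np.abs(spec.lambda_hat - target) <= tol))


def cloude_mixture(weights: np.ndarray, components: np.ndarray) -> np.ndarray:
    """Convex sum of pure Mueller matrices: M = sum_i w_i M_i.

    ``components`` may also be a validated :class:`PureComponentSet`.  The
    result is physically realizable (covariance eigenvalues >= 0 up to
    numerical noise) by construction.
    """
    if isinstance(components, PureComponentSet):
        weights, components = components.weights, components.components
    weights = np.asarray(weights, dtype=float)
    components = np.asarray(components, dtype=float)
    if np.any(weights < -1e-12) or abs(weights.sum() - 1.0) > 1e-9:
        raise ValueError("weights must be convex: non-negative and summing to 1")
    return np.einsum("i,i...->...", weights, components)


def random_pure_mueller(rng: np.random.Generator, n: int | None = None) -> np.ndarray:
    """Random non-depolarizing Mueller matrices with m00 = 1.

    Jones matrices with i.i.d. complex normal entries are mapped to Mueller
    matrices and normalized.  Returns one (4, 4) matrix or an (n, 4, 4) stack.
    """
    shape = (2, 2) if n is None else (n, 2, 2)
    J = rng.normal(size=shape) + 1j * rng.normal(size=shape)
    M = jones_to_mueller(J)
    return M / M[..., 0:1, 0:1]


def random_cloude_mixture(rng: np.random.Generator, n: int | None = None) -> np.ndarray:
    """Random physically realizable matrices: Dirichlet-weighted convex sums
    of four random pure components each.  Returns (4, 4) or (n, 4, 4)."""
    m = 1 if n is None else n
    comps = random_pure_mueller(rng, 4 * m).reshape(m, 4, 4, 4)
    w = rng.dirichlet(np.ones(4), size=m)  # (m, 4)
    M = np.einsum("mi,mijk->mjk", w, comps)
    return M[0] if n is None else M


def half_plane_labels(shape: tuple[int, int], frac: float = 0.5) -> np.ndarray:
    """Two-class layout: top fraction of rows is class 0, the rest class 1."""
    h, w = shape
    labels = np.ones(shape, dtype=np.int64)
    labels[: int(round(frac * h))] = 0
    return labels


def stripe_labels(shape: tuple[int, int], period: int, n_classes: int = 2) -> np.ndarray:
    """Horizontal stripes of ``period`` rows cycling through the classes
    (emulates ring-like structures such as tracheal cartilage)."""
    if period < 1:
        raise ValueError("stripe period must be >= 1")
    rows = (np.arange(shape[0]) // period) % n_classes
    return np.broadcast_to(rows[:, None], shape).astype(np.int64).copy()


def disk_labels(
    shape: tuple[int, int],
    centers: list[tuple[float, float]],
    radii: list[float],
    background: int = 0,
) -> np.ndarray:
    """Disks (class 1, 2, ... in order) on a uniform background (emulates
    lesions on a lamina).  Centers are (x, y) in pixels."""
    if len(centers) != len(radii):
        raise ValueError("need one radius per center")
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    labels = np.full(shape, background, dtype=np.int64)
    for k, ((cx, cy), r) in enumerate(zip(centers, radii), start=1):
        labels[(xx - cx) ** 2 + (yy - cy) ** 2 <= r * r] = k
    return labels


def generate_scene(
    layout: np.ndarray | str,
    class_matrices: np.ndarray,
    noise_sd: float = 0.0,
    seed: int | None = None,
    shape: tuple[int, int] = (256, 256),
) -> tuple[MuellerImage, SyntheticScene]:
    """Piecewise-constant Mueller image with element-wise Gaussian noise.

    ``layout`` is either an integer label map or one of the named layouts
    'half_plane', 'stripes' (period = height // 8) or 'disks' (one centered
    disk per non-background class).  Noise of scale ``noise_sd * m00`` is
    added independently to every element; identical inputs and seed give
    bit-identical scenes.
    """
    class_matrices = np.asarray(class_matrices, dtype=float)
    if class_matrices.ndim != 3 or class_matrices.shape[-2:] != (4, 4):
        raise ValueError("class_matrices must have shape (k, 4, 4)")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    k = class_matrices.shape[0]
    if isinstance(layout, str):
        if layout == "half_plane":
            labels = half_plane_labels(shape)
        elif layout == "stripes":
            labels = stripe_labels(shape, period=max(shape[0] // 8, 1), n_classes=k)
        elif layout == "disks":
            h, w = shape
            n_disks = max(k - 1, 1)
            centers = [
                (w * (i + 1) / (n_disks + 1), h / 2) for i in range(n_disks)
            ]
            radii = [min(h, w) / (3 * n_disks)] * n_disks
            labels = disk_labels(shape, centers, radii)
        else:
            raise ValueError(f"unknown layout {layout!r}")
    else:
        labels = np.asarray(layout, dtype=np.int64)
    if labels.min() < 0 or labels.max() >= k:
        raise ValueError("label map indexes a class with no matrix")

    elements = class_matrices[labels]  # (H, W, 4, 4)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        scale = noise_sd * elements[..., 0:1, 0:1]  # per-pixel m00
        elements = elements + rng.normal(size=elements.shape) * scale
        # additive noise may push m00 slightly negative at very low
        # intensity; those pixels carry no usable signal
        elements[..., 0, 0] = np.clip(elements[..., 0, 0], 0.0, None)
    image = MuellerImage(elements=np.ascontiguousarray(elements))
    scene = SyntheticScene(
        label_map=labels, class_matrices=class_matrices, noise_sd=float(noise_sd), seed=seed
    )
    return image, scene
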