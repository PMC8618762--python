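"""Sphere discretization, angular neighborhoods, and the Gaussian-mixture
response dictionary.

The diffusion signal of a single coherent fiber population is modelled as a
Gaussian with an axially symmetric tensor ``D(d)`` whose principal axis is the
fiber direction ``d``.  The dictionary ``Phi`` collects the responses of ``n``
candidate fiber orientations (one hemisphere of the unit sphere; directions
are axial, so ``d`` and ``-d`` are identified) plus two isotropic atoms for
gray matter and CSF.  Row one of ``Phi`` corresponds to the b=0 measurement
and is identically 1, which — together with a matching unit row in the data —
forces the per-voxel volume-fraction coefficients to sum to one.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DirectionSet",
    "GradientScheme",
    "Dictionary",
    "AngularNeighborhood",
    "sample_hemisphere",
    "rotate_tensor",
    "build_dictionary",
    "angular_neighbors",
    "axial_angle_deg",
    "WM_DIFFUSIVITIES",
    "GM_ISO_DIFFUSIVITY",
    "CSF_ISO_DIFFUSIVITY",
]

# White-matter single-fiber tensor eigenvalues and the two isotropic
# diffusivities, in mm^2/s.
WM_DIFFUSIVITIES: tuple[float, float, float] = (17e-4, 3e-4, 3e-4)
GM_ISO_DIFFUSIVITY: float = 17e-4
CSF_ISO_DIFFUSIVITY: float = 30e-4


@dataclass(frozen=True)
class DirectionSet:
    """``n`` unit vectors on one hemisphere, identified axially (d ~ -d)."""

    directions: np.ndarray  # (n, 3)

    def __post_init__(self) -> None:
        d = np.asarray(self.directions, dtype=float)
        if d.ndim != 2 or d.shape[1] != 3 or d.shape[0] < 1:
            raise ValueError("directions must be an (n, 3) array with n >= 1")
        norms = np.linalg.norm(d, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-12):
            raise ValueError("all directions must have unit norm")
        object.__setattr__(self, "directions", d)

    @property
    def n(self) -> int:
        return self.directions.shape[0]


@dataclass(frozen=True)
class GradientScheme:
    """Diffusion gradient table: b-values (s/mm^2) and unit directions.

    Entry 0 is the b=0 (s0) measurement by convention.
    """

    bvals: np.ndarray  # (M,)
    bvecs: np.ndarray  # (M, 3)
    diffusion_time: float | None = None

    def __post_init__(self) -> None:
        b = np.asarray(self.bvals, dtype=float)
        v = np.asarray(self.bvecs, dtype=float)
        if b.ndim != 1 or v.shape != (b.size, 3):
            raise ValueError("bvals must be (M,) and bvecs (M, 3)")
        if b[0] != 0:
            raise ValueError("entry 0 must be the b=0 measurement")
        dw = b > 0
        if dw.any() and not np.allclose(np.linalg.norm(v[dw], axis=1), 1.0, atol=1e-8):
            raise ValueError("diffusion-weighted bvecs must have unit norm")
        object.__setattr__(self, "bvals", b)
        object.__setattr__(self, "bvecs", v)

    @property
    def M(self) -> int:
        return self.bvals.size


@dataclass(frozen=True)
class Dictionary:
    """Response matrix ``Phi`` of shape (M, n+2); last two columns isotropic."""

    matrix: np.ndarray
    direction_set: DirectionSet
    diffusivities: dict = field(default_factory=dict)

    @property
    def n(self) -> int:
        return self.direction_set.n

    @property
    def M(self) -> int:
        return self.matrix.shape[0]


@dataclass(frozen=True)
class AngularNeighborhood:
    """For each direction index d, the set N(d) of indices within a cone."""

    cone_degrees: float
    adjacency: list  # list of np.ndarray of int indices

    def matrix(self, n: int) -> np.ndarray:
        """Dense boolean adjacency matrix (n, n)."""
        A = np.zeros((n, n), dtype=bool)
        for d, nbrs in enumerate(self.adjacency):
            A[d, nbrs] = True
        return A


def axial_angle_deg(u: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Axial angle arccos(|u.v|) in degrees between unit vectors.

    Broadcasts over leading dimensions; directions are orientations, so the
    angle never exceeds 90 degrees.
    """
    dot = np.abs(np.sum(np.asarray(u) * np.asarray(v), axis=-1))
    return np.degrees(np.arccos(np.clip(dot, -1.0, 1.0)))


def sample_hemisphere(n: int, seed: int = 0) -> DirectionSet:
    """Quasi-uniform axial directions via a spherical-Fibonacci lattice.

    The lattice places n points with z strictly in (0, 1) — equal-area
    latitudes with golden-angle longitudes — so every point lies in the open
    upper hemisphere and no two are antipodal.  The construction is
    deterministic; ``seed`` only permutes the labelling so that downstream
    seeded experiments decorrelate.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    i = np.arange(n)
    golden = (1 + np.sqrt(5.0)) / 2
    z = (2 * i + 1) / (2 * n)          # in (0, 1): open upper hemisphere
    phi = 2 * np.pi * (i / golden % 1.0)
    r = np.sqrt(np.maximum(0.0, 1 - z * z))
    pts = np.column_stack([r * np.cos(phi), r * np.sin(phi), z])
    pts /= np.linalg.norm(pts, axis=1, keepdims=True)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    return DirectionSet(pts[perm])


def _rotation_to(d: np.ndarray) -> np.ndarray:
    """Rotation matrix carrying the reference axis e_z to unit vector d
    (Rodrigues construction)."""
    d = np.asarray(d, dtype=float)
    ez = np.array([0.0, 0.0, 1.0])
    c = float(np.dot(ez, d))
    if c > 1 - 1e-14:
        return np.eye(3)
    if c < -1 + 1e-14:
        # 180-degree rotation about x.
        return np.diag([1.0, -1.0, -1.0])
    axis = np.cross(ez, d)
    s = np.linalg.norm(axis)
    axis /= s
    K = np.array([
        [0, -axis[2], axis[1]],
        [axis[2], 0, -axis[0]],
        [-axis[1], axis[0], 0],
    ])
    return np.eye(3) + s * K + (1 - c) * (K @ K)


def rotate_tensor(d: np.ndarray, lambdas: tuple[float, float, float]) -> np.ndarray:
    """Axially symmetric diffusion tensor with principal axis d.

    Returns R diag(l1, l2, l3) R^T where R carries the reference axis to d.
    With l2 == l3 the result does not depend on the choice of R.
    """
    d = np.asarray(d, dtype=float)
    if abs(np.linalg.norm(d) - 1.0) > 1e-10:
        raise ValueError("d must be a unit vector")
    l1, l2, l3 = lambdas
    if min(l1, l2, l3) <= 0:
        raise ValueError("diffusivities must be positive")
    R = _rotation_to(d)
    # Reference tensor carries the longitudinal diffusivity l1 along e_z,
    # which R maps to d; l2 and l3 are transverse.
    return R @ np.diag([l2, l3, l1]) @ R.T


def build_dictionary(
    scheme: GradientScheme,
    dirs: DirectionSet,
    lambda_wm: tuple[float, float, float] = WM_DIFFUSIVITIES,
    lambda_gm_iso: float = GM_ISO_DIFFUSIVITY,
    lambda_csf_iso: float = CSF_ISO_DIFFUSIVITY,
) -> Dictionary:
    """Gaussian-mixture dictionary Phi with entries exp(-b qhat^T D(d) qhat).

    Columns 0..n-1 are single-fiber atoms (rotated WM tensor), column n the
    gray-matter isotropic atom, column n+1 the CSF isotropic atom.  The b=0
    row is identically 1.
    """
    b = scheme.bvals[:, None]                       # (M, 1)
    q = scheme.bvecs                                # (M, 3)
    D = np.stack([rotate_tensor(d, lambda_wm) for d in dirs.directions])  # (n,3,3)
    # quadratic form qhat^T D(d) qhat for every (gradient, direction) pair
    quad = np.einsum("mi,dij,mj->md", q, D, q)      # (M, n)
    fiber = np.exp(-b * quad)
    gm = np.exp(-b * lambda_gm_iso)
    csf = np.exp(-b * lambda_csf_iso)
    matrix = np.hstack([fiber, gm, csf])
    matrix[scheme.bvals == 0] = 1.0                 # exact, not just exp(-0)
    return Dictionary(
        matrix=matrix,
        direction_set=dirs,
        diffusivities={
            "wm": tuple(lambda_wm),
            "gm_iso": lambda_gm_iso,
            "csf_iso": lambda_csf_iso,
        },
    )


def angular_neighbors(dirs: DirectionSet, cone_degrees: float = 15.0) -> AngularNeighborhood:
    """Cone neighborhoods N(d) = {d' : axial angle(d, d') <= cone_degrees}."""
    if not 0 < cone_degrees < 90:
        raise ValueError("cone_degrees must lie in (0, 90)")
    d = dirs.directions
    ang = axial_angle_deg(d[:, None, :], d[None, :, :])
    adjacency = [np.nonzero(ang[i] <= cone_degrees)[0] for i in range(dirs.n)]
    return AngularNeighborhood(cone_degrees=cone_degrees, adjacency=adjacency)
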