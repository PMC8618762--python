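"""Measurement operator for multi-coil under-sampled kq-space data.

For gradient q and coil c the operator maps the FOD coefficient field
X (shape (n+2, N)) to k-space samples

    A_{q,c}(X) = mask_q [ FFT3( Phi_q X  *  s0  *  U_c  *  H_{q,c} ) ]

where Phi_q is row q of the response dictionary, s0 the b=0 volume, U_c the
coil sensitivity, H_{q,c} a unit-modulus phase map and FFT3 the unitary 3D
Fourier transform with DC at the grid center.  The tissue embedding Z maps
the compact per-tissue unknowns S = (S1, S2, S3) — white-matter fiber
coefficients, gray-matter and CSF isotropic fractions — into X, writing
zeros wherever the segmentation excludes a tissue.

Conventions fixed here and relied on throughout: unitary FFT (adjoint =
inverse on full masks), C-order volume flattening, 0-based indices, masks as
sample selectors (zero-filling only in adjoints), and the true gradient of
the data-fit ||A Z(S) - Y||^2 including its factor 2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dictionary import Dictionary
from .phantom import CoilProfiles, PhaseMaps
from .sampling import SamplingMask

__all__ = [
    "FODField",
    "SplitFOD",
    "TissueMaps",
    "AcquisitionModel",
    "KSpaceData",
    "fft3",
    "ifft3",
    "embed",
    "restrict",
    "apply_A",
    "apply_A_coil",
    "adjoint_A",
    "adjoint_A_coil",
    "coil_gradient",
    "coil_gradients",
    "data_fidelity",
    "spectral_norm",
]


_AXES = (-3, -2, -1)
_checker_cache: dict = {}


def _checkerboard(shape: tuple) -> np.ndarray:
    """(-1)^(x+y+z) over the last-3-axes grid (cached per shape)."""
    if shape not in _checker_cache:
        nx, ny, nz = shape
        g = (
            (-1.0) ** np.arange(nx)[:, None, None]
            * (-1.0) ** np.arange(ny)[None, :, None]
            * (-1.0) ** np.arange(nz)[None, None, :]
        )
        _checker_cache[shape] = g
    return _checker_cache[shape]


def fft3(vol: np.ndarray) -> np.ndarray:
    """Unitary 3D FFT with DC at the grid center (acts on last 3 axes).

    For even grid dimensions the centering shifts reduce to checkerboard
    sign flips (up to a constant global sign), which is much cheaper than
    rolling the arrays; odd dimensions fall back to explicit shifts.
    """
    from scipy import fft as sfft

    shape = vol.shape[-3:]
    if all(s % 2 == 0 for s in shape):
        T = _checkerboard(shape)
        sign = (-1.0) ** (sum(s // 2 for s in shape))
        return sign * T * sfft.fftn(T * vol, axes=_AXES, norm="ortho")
    return np.fft.fftshift(
        sfft.fftn(np.fft.ifftshift(vol, axes=_AXES), axes=_AXES, norm="ortho"),
        axes=_AXES,
    )


def ifft3(kvol: np.ndarray) -> np.ndarray:
    from scipy import fft as sfft

    shape = kvol.shape[-3:]
    if all(s % 2 == 0 for s in shape):
        T = _checkerboard(shape)
        sign = (-1.0) ** (sum(s // 2 for s in shape))
        return sign * T * sfft.ifftn(T * kvol, axes=_AXES, norm="ortho")
    return np.fft.fftshift(
        sfft.ifftn(np.fft.ifftshift(kvol, axes=_AXES), axes=_AXES, norm="ortho"),
        axes=_AXES,
    )


@dataclass
class TissueMaps:
    """Disjoint WM/GM/CSF masks with cached flat index lists."""

    wm: np.ndarray
    gm: np.ndarray
    csf: np.ndarray

    def __post_init__(self) -> None:
        if (self.wm & self.gm).any() or (self.wm & self.csf).any() or (
            self.gm & self.csf
        ).any():
            raise ValueError("tissue maps must be disjoint")
        self.wm_idx = np.nonzero(self.wm.ravel())[0]
        self.gm_idx = np.nonzero(self.gm.ravel())[0]
        self.csf_idx = np.nonzero(self.csf.ravel())[0]

    @classmethod
    def from_dict(cls, maps: dict) -> "TissueMaps":
        return cls(wm=maps["wm"], gm=maps["gm"], csf=maps["csf"])

    @property
    def counts(self) -> tuple[int, int, int]:
        return self.wm_idx.size, self.gm_idx.size, self.csf_idx.size


@dataclass
class SplitFOD:
    """Tissue-partitioned unknowns: S1 (n, N1) WM, S2 (N2,) GM, S3 (N3,) CSF."""

    S1: np.ndarray
    S2: np.ndarray
    S3: np.ndarray

    def copy(self) -> "SplitFOD":
        return SplitFOD(self.S1.copy(), self.S2.copy(), self.S3.copy())

    def norm(self) -> float:
        return float(
            np.sqrt(
                np.sum(self.S1**2) + np.sum(self.S2**2) + np.sum(self.S3**2)
            )
        )

    def axpy(self, alpha: float, other: "SplitFOD") -> "SplitFOD":
        """self + alpha * other, returned as a new SplitFOD."""
        return SplitFOD(
            self.S1 + alpha * other.S1,
            self.S2 + alpha * other.S2,
            self.S3 + alpha * other.S3,
        )

    @classmethod
    def zeros(cls, n: int, tissues: TissueMaps) -> "SplitFOD":
        N1, N2, N3 = tissues.counts
        return cls(np.zeros((n, N1)), np.zeros(N2), np.zeros(N3))


FODField = np.ndarray  # (n+2, N) nonnegative coefficients


@dataclass
class KSpaceData:
    """Per-gradient stacks of per-coil masked k-space samples."""

    samples: list  # samples[q]: complex array (C, K_q)

    def copy(self) -> "KSpaceData":
        return KSpaceData([s.copy() for s in self.samples])

    def norm2(self) -> float:
        return float(sum(np.sum(np.abs(s) ** 2) for s in self.samples))


@dataclass
class AcquisitionModel:
    """Everything defining the operator A."""

    dictionary: Dictionary
    s0: np.ndarray               # volume, shape grid_shape
    coils: CoilProfiles
    phases: PhaseMaps
    masks: list                  # one SamplingMask per gradient
    grid_shape: tuple

    def __post_init__(self) -> None:
        self.grid_shape = tuple(self.grid_shape)
        self.N = int(np.prod(self.grid_shape))
        self.M = self.dictionary.M
        self.C = self.coils.C
        if self.s0.shape != self.grid_shape:
            raise ValueError("s0 shape does not match grid")
        if self.phases.maps.shape != (self.M, self.C) + self.grid_shape:
            raise ValueError("phase maps must have shape (M, C, *grid)")
        if len(self.masks) != self.M:
            raise ValueError("need one mask per gradient")
        self._mask_arrays = [m.as_array() for m in self.masks]
        # Per-(q,c) spatial factor s0 * U_c * H_qc, flat over voxels.
        s0f = self.s0.reshape(-1)
        Uf = self.coils.maps.reshape(self.C, -1)
        Hf = self.phases.maps.reshape(self.M, self.C, -1)
        self._spatial = s0f[None, None, :] * Uf[None, :, :] * Hf  # (M, C, N)


def embed(S: SplitFOD, tissues: TissueMaps, n: int, N: int) -> FODField:
    """Tissue embedding Z: scatter S into the full (n+2, N) field."""
    X = np.zeros((n + 2, N))
    X[:n, tissues.wm_idx] = S.S1
    X[n, tissues.gm_idx] = S.S2
    X[n + 1, tissues.csf_idx] = S.S3
    return X

def restrict(X: FODField, tissues: TissueMaps) -> SplitFOD:
    """Adjoint (and left inverse) of the embedding: gather tissue blocks."""
    n = X.shape[0] - 2
    return SplitFOD(
        S1=X[:n, tissues.wm_idx].copy(),
        S2=X[n, tissues.gm_idx].copy(),
        S3=X[n + 1, tissues.csf_idx].copy(),
    )


def apply_A_coil(X: FODField, model: AcquisitionModel, c: int) -> list:
    """Samples for one coil: list over q of complex (K_q,) vectors."""
    P = model.dictionary.matrix @ X                       # (M, N)
    out = []
    for q in range(model.M):
        vol = (P[q] * model._spatial[q, c]).reshape(model.grid_shape)
        out.append(fft3(vol)[model._mask_arrays[q]])
    return out


def apply_A(X: FODField, model: AcquisitionModel) -> KSpaceData:
    """Full measurement: per gradient a (C, K_q) stack of samples."""
    if X.shape != (model.dictionary.matrix.shape[1], model.N):
        raise ValueError("X shape does not match model")
    P = model.dictionary.matrix @ X                       # (M, N)
    samples = []
    for q in range(model.M):
        vols = (P[q][None, :] * model._spatial[q]).reshape(
            (model.C,) + model.grid_shape
        )
        khat = fft3(vols)
        samples.append(khat[:, model._mask_arrays[q]])
    return KSpaceData(samples)


def adjoint_A_coil(samples_c: list, model: AcquisitionModel, c: int) -> FODField:
    """Adjoint for one coil's samples (list over q of (K_q,) vectors)."""
    V = np.empty((model.M, model.N))
    kvol = np.zeros(model.grid_shape, dtype=complex)
    for q in range(model.M):
        kvol[...] = 0
        kvol[model._mask_arrays[q]] = samples_c[q]
        img = ifft3(kvol).reshape(-1)
        V[q] = np.real(np.conj(model._spatial[q, c]) * img)
    return model.dictionary.matrix.T @ V


def adjoint_A(Y: KSpaceData, model: AcquisitionModel) -> FODField:
    """Exact adjoint of apply_A under the real inner product on X."""
    V = np.zeros((model.M, model.N))
    for q in range(model.M):
        kvols = np.zeros((model.C,) + model.grid_shape, dtype=complex)
        kvols[:, model._mask_arrays[q]] = Y.samples[q]
        imgs = ifft3(kvols).reshape(model.C, -1)
        V[q] = np.sum(np.real(np.conj(model._spatial[q]) * imgs), axis=0)
    return model.dictionary.matrix.T @ V


def coil_gradient(
    S: SplitFOD, Y: KSpaceData, model: AcquisitionModel, tissues: TissueMaps, c: int
) -> SplitFOD:
    """Gradient of ||A_c Z(S) - Y_c||^2 with the factor 2 kept explicit."""
    return coil_gradients(S, Y, model, tissues, [c])[0]


def coil_gradients(
    S: SplitFOD,
    Y: KSpaceData,
    model: AcquisitionModel,
    tissues: TissueMaps,
    subset,
) -> list:
    """Per-coil gradients for a subset of coils, sharing the Phi X product
    and batching FFTs across the subset."""
    subset = np.asarray(subset, dtype=int)
    n = model.dictionary.matrix.shape[1] - 2
    X = embed(S, tissues, n, model.N)
    P = model.dictionary.matrix @ X                       # (M, N)
    k = subset.size
    spatial = model._spatial[:, subset, :]                # (M, k, N)
    vols = (P[:, None, :] * spatial).reshape((model.M * k,) + model.grid_shape)
    khat = fft3(vols).reshape((model.M, k) + model.grid_shape)
    # Masked residual, zero-filled off-mask (masks are ragged across q).
    resid = np.zeros_like(khat)
    for q in range(model.M):
        mask = model._mask_arrays[q]
        resid[q][:, mask] = khat[q][:, mask] - Y.samples[q][subset]
    imgs = ifft3(resid.reshape((model.M * k,) + model.grid_shape))
    V = np.real(np.conj(spatial) * imgs.reshape(model.M, k, model.N))
    G = np.tensordot(model.dictionary.matrix.T, V, axes=(1, 0))  # (n+2, k, N)
    return [restrict(2.0 * G[:, i, :], tissues) for i in range(k)]


def data_fidelity(
    S: SplitFOD, Y: KSpaceData, model: AcquisitionModel, tissues: TissueMaps
) -> float:
    """||A Z(S) - Y||^2 over all gradients and coils."""
    n = model.dictionary.matrix.shape[1] - 2
    X = embed(S, tissues, n, model.N)
    pred = apply_A(X, model)
    return float(
        sum(
            np.sum(np.abs(pred.samples[q] - Y.samples[q]) ** 2)
            for q in range(model.M)
        )
    )


def spectral_norm(
    model: AcquisitionModel,
    tissues: TissueMaps | None = None,
    tol: float = 1e-6,
    max_iter: int = 1000,
    seed: int = 0,
) -> float:
    """Power-method estimate of ||A o Z||_S (largest singular value).

    With ``tissues`` None the norm of A itself (identity embedding over all
    voxels, all rows) is estimated.  Emits a warning on non-convergence and
    returns the best estimate.
    """
    import warnings

    rng = np.random.default_rng(seed)
    n = model.dictionary.matrix.shape[1] - 2
    if tissues is None:
        x = rng.standard_normal((n + 2, model.N))
        x /= np.linalg.norm(x)
        lam = 0.0
        for _ in range(max_iter):
            y = adjoint_A(apply_A(x, model), model)
            lam_new = float(np.sqrt(np.sum(x * y)))
            nrm = np.linalg.norm(y)
            if nrm == 0:
                return 0.0
            x = y / nrm
            if abs(lam_new - lam) <= tol * max(lam_new, 1e-30):
                return lam_new
            lam = lam_new
        warnings.warn("spectral_norm: power method did not converge")
        return lam
    S = SplitFOD(
        rng.standard_normal((n, tissues.wm_idx.size)),
        rng.standard_normal(tissues.gm_idx.size),
        rng.standard_normal(tissues.csf_idx.size),
    )
    nrm = S.norm()
    S = SplitFOD(S.S1 / nrm, S.S2 / nrm, S.S3 / nrm)
    lam = 0.0
    for _ in range(max_iter):
        X = embed(S, tissues, n, model.N)
        G = restrict(adjoint_A(apply_A(X, model), model), tissues)
        lam_new = float(
            np.sqrt(
                np.sum(S.S1 * G.S1) + np.sum(S.S2 * G.S2) + np.sum(S.S3 * G.S3)
            )
        )
        nrm = G.norm()
        if nrm == 0:
            return 0.0
        S = SplitFOD(G.S1 / nrm, G.S2 / nrm, G.S3 / nrm)
        if abs(lam_new - lam) <= tol * max(lam_new, 1e-30):
            return lam_new
        lam = lam_new
    warnings.warn("spectral_norm: power method did not converge")
    return lam
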