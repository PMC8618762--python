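"""Comparison reconstruction methods.

Two-step pipelines first recover the complex diffusion-weighted (DW) images
from k-space with a total-variation (TV) penalty, take magnitudes, normalize
by s0, and then fit the FOD per voxel — either by nonnegative least squares
(TV-L2+) or with the structured-sparsity reweighted-l1 solver in q-space
(TV-STR+).  The one-step TV+ method reconstructs the FOD field directly from
kq-space with a TV penalty on the predicted DW volumes and a positivity
constraint, via a primal-dual (Condat-Vu) iteration with an explicit
gradient on the smooth data term.

TV is isotropic 3D total variation with forward differences and Neumann
boundaries throughout.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.optimize import nnls

from .dictionary import AngularNeighborhood, Dictionary
from .forward_model import (
    AcquisitionModel,
    KSpaceData,
    SplitFOD,
    TissueMaps,
    adjoint_A,
    apply_A,
    embed,
    fft3,
    ifft3,
    restrict,
    spectral_norm,
)
from .phantom import CoilProfiles, PhaseMaps
from .sampling import kmask_two_phase
from .solver import SolverConfig, reweighted_solve

__all__ = [
    "tv_grad",
    "tv_div",
    "tv_recover_images",
    "nnls_fod",
    "str_fod_qspace",
    "tv_plus_onestep",
    "grid_search",
]

# Documented grid-search ranges for the baseline regularization parameters
# (two-step image recovery lambda, one-step TV+ lambda, q-space ball radius
# kappa as a per-voxel multiple).
TV_STEP1_LAMBDA_RANGE = (1e3, 2.1e3)
TV_PLUS_LAMBDA_RANGE = (4e5, 9.8e5)
STR_KAPPA_PER_VOXEL_RANGE = (3.9, 4.2)


def tv_grad(vol: np.ndarray) -> np.ndarray:
    """Forward differences along the 3 axes, Neumann boundary (last slice 0)."""
    g = np.zeros((3,) + vol.shape, dtype=vol.dtype)
    g[0, :-1] = vol[1:] - vol[:-1]
    g[1, :, :-1] = vol[:, 1:] - vol[:, :-1]
    g[2, :, :, :-1] = vol[:, :, 1:] - vol[:, :, :-1]
    return g


def tv_div(p: np.ndarray) -> np.ndarray:
    """Negative adjoint of tv_grad: tv_div(tv_grad(v)) is the discrete
    Laplacian; <tv_grad(u), p> = -<u, tv_div(p)>."""
    out = np.zeros(p.shape[1:], dtype=p.dtype)
    out[:-1] += p[0, :-1]
    out[1:] -= p[0, :-1]
    out[:, :-1] += p[1, :, :-1]
    out[:, 1:] -= p[1, :, :-1]
    out[:, :, :-1] += p[2, :, :, :-1]
    out[:, :, 1:] -= p[2, :, :, :-1]
    return out


def _proj_dual_ball(p: np.ndarray, lam: float) -> np.ndarray:
    """Pointwise projection onto the l2 ball of radius lam (isotropic TV dual)."""
    mag = np.sqrt(np.sum(np.abs(p) ** 2, axis=0))
    scale = np.maximum(1.0, mag / lam) if lam > 0 else np.inf
    if lam == 0:
        return np.zeros_like(p)
    return p / scale[None]


def tv_recover_images(
    Y: KSpaceData,
    model: AcquisitionModel,
    lam: float,
    n_iter: int = 300,
    tol: float = 1e-6,
) -> tuple[np.ndarray, np.ndarray]:
    """Step 1 of the two-step pipelines: TV-regularized SENSE recovery.

    Solves, independently per gradient q,
        min_I  sum_c || mask_q FFT(U_c I) - Y_{q,c} ||^2 + lam ||I||_TV
    by Condat-Vu (explicit gradient on the smooth data term, dual update on
    the TV term).  Phase contamination is deliberately not modelled: the
    magnitude is taken afterwards, as two-step methods do.

    Returns ``(I, I_norm)``: complex DW volumes (M, N) and their magnitudes
    normalized by s0 (zero where s0 is), ready for the q-space FOD step.
    """
    if lam < 0:
        raise ValueError("lam must be >= 0")
    C = model.C
    U = model.coils.maps                             # (C, *grid)
    sos = np.sum(np.abs(U) ** 2, axis=0)
    L = 2.0 * float(sos.max())                       # Lipschitz of the data grad
    sigma = (L / 2.0) / 12.0 if lam > 0 else 0.0
    tau = 0.95 / (L / 2.0 + sigma * 12.0 + 1e-12)    # strictly inside the
    # Condat-Vu stability region (1/tau - sigma ||D||^2 > L/2)
    I = np.zeros((model.M,) + model.grid_shape, dtype=complex)
    for q in range(model.M):
        mask = model._mask_arrays[q]
        Iq = np.zeros(model.grid_shape, dtype=complex)
        p = np.zeros((3,) + model.grid_shape, dtype=complex)
        prev_obj = np.inf
        for it in range(n_iter):
            # gradient of the data term
            pred = fft3(U * Iq[None])
            resid = np.zeros_like(pred)
            resid[:, mask] = pred[:, mask] - Y.samples[q]
            grad = 2.0 * np.sum(np.conj(U) * ifft3(resid), axis=0)
            Iq_new = Iq - tau * (grad - tv_div(p))
            if lam > 0:
                p = _proj_dual_ball(p + sigma * tv_grad(2 * Iq_new - Iq), lam)
            delta = np.linalg.norm(Iq_new - Iq) / max(np.linalg.norm(Iq_new), 1e-30)
            Iq = Iq_new
            if delta < tol:
                break
        else:
            if lam > 0:
                warnings.warn(f"tv_recover_images: gradient {q} hit n_iter")
        I[q] = Iq
    s0 = model.s0
    I_norm = np.zeros((model.M, model.N))
    nz = (s0 > 0).reshape(-1)
    I_norm[:, nz] = np.abs(I.reshape(model.M, -1))[:, nz] / s0.reshape(-1)[nz]
    return I.reshape(model.M, -1), I_norm


def nnls_fod(
    I_norm: np.ndarray,
    dictionary: Dictionary,
    voxel_mask: np.ndarray | None = None,
) -> np.ndarray:
    """Step 2 of TV-L2+: per-voxel nonnegative least squares on the
    normalized DW signals.  Returns an (n+2, N) field (zeros off-mask)."""
    Phi = dictionary.matrix
    M, N = I_norm.shape
    if Phi.shape[0] != M:
        raise ValueError("dictionary and image rows disagree")
    X = np.zeros((Phi.shape[1], N))
    cols = range(N) if voxel_mask is None else np.nonzero(voxel_mask.reshape(-1))[0]
    for v in cols:
        X[:, v], _ = nnls(Phi, I_norm[:, v])
    return X


def _identity_model(
    dictionary: Dictionary, grid_shape: tuple
) -> AcquisitionModel:
    """Acquisition model reducing A to a unitary FFT of Phi X: full masks,
    one unit coil, zero phase, unit s0."""
    M = dictionary.M
    masks = [
        kmask_two_phase(grid_shape, 1.0, 1, gradient_index=q) for q in range(M)
    ]
    coils = CoilProfiles(maps=np.ones((1,) + tuple(grid_shape), dtype=complex))
    phases = PhaseMaps(maps=np.ones((M, 1) + tuple(grid_shape), dtype=complex))
    return AcquisitionModel(
        dictionary=dictionary,
        s0=np.ones(grid_shape),
        coils=coils,
        phases=phases,
        masks=masks,
        grid_shape=tuple(grid_shape),
    )


def str_fod_qspace(
    I_norm: np.ndarray,
    dictionary: Dictionary,
    tissues: TissueMaps,
    config: SolverConfig,
    grid_shape: tuple,
    angular: AngularNeighborhood | None = None,
) -> SplitFOD:
    """Step 2 of TV-STR+: reweighted structured-sparsity FOD fit in q-space.

    Reuses the main solver with a trivialized acquisition model (full masks,
    one unit coil, zero phase, unit s0): the unitary FFT makes the k-space
    data fit equal the q-space fit ||Phi X - I_norm||^2 exactly.
    """
    model = _identity_model(dictionary, grid_shape)
    vols = I_norm.reshape((dictionary.M,) + tuple(grid_shape))
    samples = [fft3(vols[q].astype(complex))[None, :].reshape(1, -1) for q in range(dictionary.M)]
    # masks are full: sample vectors are the whole grid per gradient
    Y = KSpaceData([s.reshape(1, -1) for s in samples])
    return reweighted_solve(Y, model, tissues, config, angular=angular)


def tv_plus_onestep(
    Y: KSpaceData,
    model: AcquisitionModel,
    lam: float,
    n_iter: int = 300,
    tol: float = 1e-6,
) -> np.ndarray:
    """One-step TV+ reconstruction:

        min_{X >= 0}  || A(X) - Y ||^2 + lam || Phi X ||_TV

    solved with a Condat-Vu primal-dual iteration: explicit factor-2 gradient
    on the data term, positivity clip in the primal prox, pointwise dual-ball
    projection for the isotropic TV term applied to each predicted DW volume.
    Returns the (n+2, N) FOD field.
    """
    if lam < 0:
        raise ValueError("lam must be >= 0")
    Phi = model.dictionary.matrix
    n2 = Phi.shape[1]
    norm_A = spectral_norm(model, seed=0)
    L = 2.0 * norm_A**2
    normK2 = 12.0 * float(np.linalg.norm(Phi, 2)) ** 2
    sigma = (L / 2.0) / normK2 if lam > 0 else 0.0
    tau = 0.95 / (L / 2.0 + sigma * normK2 + 1e-12)
    X = np.zeros((n2, model.N))
    p = np.zeros((model.M, 3) + model.grid_shape)
    for it in range(n_iter):
        pred = apply_A(X, model)
        for q in range(model.M):
            pred.samples[q] = pred.samples[q] - Y.samples[q]
        grad = 2.0 * adjoint_A(pred, model)
        if lam > 0:
            div = np.stack([tv_div(p[q]).reshape(-1) for q in range(model.M)])
            grad = grad - Phi.T @ div
        X_new = np.maximum(X - tau * grad, 0.0)
        if lam > 0:
            V = (Phi @ (2 * X_new - X)).reshape((model.M,) + model.grid_shape)
            for q in range(model.M):
                p[q] = _proj_dual_ball(p[q] + sigma * tv_grad(V[q]), lam)
        delta = np.linalg.norm(X_new - X) / max(np.linalg.norm(X_new), 1e-30)
        X = X_new
        if delta < tol:
            break
    else:
        warnings.warn("tv_plus_onestep hit n_iter without meeting tol")
    return X


def grid_search(values, score_fn, maximize: bool = True):
    """Pick the parameter value with the best score; returns (best, scores)."""
    scores = [score_fn(v) for v in values]
    pick = int(np.argmax(scores) if maximize else np.argmin(scores))
    return values[pick], dict(zip(values, scores))
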