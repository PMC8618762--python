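"""Ground-truthed synthetic phantom and multi-coil kq-space acquisition
simulator.

The phantom is a small brain-like volume with disjoint white-matter (WM),
gray-matter (GM) and CSF compartments arranged in concentric shells of an
ellipsoid.  WM voxels carry one to three fiber populations, including at
least one orthogonal crossing region and a small three-fiber core; GM and
CSF voxels carry mass only on their isotropic dictionary atom.  Every fiber's
mass sits on the single nearest dictionary direction so that peak-level
checks against the ground truth are exact.

The acquisition simulator applies the same physics the reconstruction
assumes: smooth complex coil sensitivities, per-gradient motion-induced
linear phase ramps whose k-space shift stays within a bounded number of
phase-encoding lines, a unitary 3D FFT, per-gradient Cartesian
under-sampling masks, and complex i.i.d. Gaussian noise in k-space with
sigma = mean(s0 over brain) / SNR per real/imaginary component.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dictionary import DirectionSet, Dictionary, GradientScheme
from .sampling import PHASE_AXIS, SamplingMask

__all__ = [
    "Phantom",
    "CoilProfiles",
    "PhaseMaps",
    "make_phantom",
    "simulate_coils",
    "simulate_phase",
    "make_phase_maps",
    "simulate_acquisition",
    "kspace_shift_lines",
]

DEFAULT_SNR = 30.0
DEFAULT_MAX_SHIFT_LINES = 10.0
DEFAULT_N_COILS = 4


@dataclass
class Phantom:
    shape: tuple
    tissue_maps: dict            # {"wm","gm","csf"}: boolean volumes
    true_fod: np.ndarray         # (n+2, N) simplex columns on tissue support
    true_peaks: dict             # flat WM voxel index -> (dirs (k,3), fracs (k,))
    s0: np.ndarray               # nonnegative volume, zero outside the brain
    direction_set: DirectionSet

    @property
    def brain_mask(self) -> np.ndarray:
        return self.tissue_maps["wm"] | self.tissue_maps["gm"] | self.tissue_maps["csf"]

    @property
    def mean_s0(self) -> float:
        """Mean of s0 over brain voxels (the SNR reference level)."""
        return float(self.s0[self.brain_mask].mean())

    @property
    def n_wm(self) -> int:
        return int(self.tissue_maps["wm"].sum())


@dataclass
class CoilProfiles:
    maps: np.ndarray             # (C, *shape) complex

    @property
    def C(self) -> int:
        return self.maps.shape[0]


@dataclass
class PhaseMaps:
    maps: np.ndarray             # (M, C, *shape) complex, unit modulus

    def __post_init__(self) -> None:
        if not np.allclose(np.abs(self.maps), 1.0, atol=1e-9):
            raise ValueError("phase maps must have unit modulus")


def _snap_to_dictionary(d: np.ndarray, dirs: DirectionSet) -> tuple[int, np.ndarray]:
    """Index and vector of the dictionary direction nearest to d (axially)."""
    dots = np.abs(dirs.directions @ d)
    idx = int(np.argmax(dots))
    return idx, dirs.directions[idx]


def make_phantom(
    shape: tuple = (16, 16, 10),
    n_crossing_regions: int = 1,
    dirs: DirectionSet | None = None,
    seed: int = 0,
) -> Phantom:
    """Build the shell phantom with fiber bands and crossing regions.

    Tissue shells by normalized ellipsoidal radius rho: WM for rho <= 0.55,
    GM for rho <= 0.8, CSF for rho <= 1, empty outside.  Each crossing region
    is a pair of orthogonal fiber bands inside the WM core (in-plane
    directions rotated per region); band overlaps host two-fiber voxels and a
    small central slab hosts a third, through-plane fiber.
    """
    if shape[0] < 8 or shape[1] < 8 or shape[2] < 4:
        raise ValueError("grid must be at least 8x8 in-plane and 4 slices")
    if dirs is None:
        from .dictionary import sample_hemisphere

        dirs = sample_hemisphere(96, seed=0)
    if n_crossing_regions < 1:
        raise ValueError("need at least one crossing region")
    shape = tuple(int(s) for s in shape)
    nx, ny, nz = shape
    xx, yy, zz = np.meshgrid(
        np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij"
    )
    cx, cy, cz = (nx - 1) / 2, (ny - 1) / 2, (nz - 1) / 2
    rho = np.sqrt(
        ((xx - cx) / (nx / 2)) ** 2
        + ((yy - cy) / (ny / 2)) ** 2
        + ((zz - cz) / (nz / 2)) ** 2
    )
    brain = rho <= 1.0
    wm = rho <= 0.55
    gm = (rho > 0.55) & (rho <= 0.8)
    csf = (rho > 0.8) & brain
    if wm.sum() < 4:
        raise ValueError("grid too small to host a crossing region")

    n = dirs.n
    N = nx * ny * nz
    X = np.zeros((n + 2, N), dtype=float)
    true_peaks: dict = {}

    rng = np.random.default_rng(seed)
    wm_idx = np.nonzero(wm.ravel())[0]
    wm_x, wm_y, wm_z = np.unravel_index(wm_idx, shape)

    # In-plane band half-width scaled to the WM core size.
    half_w = max(1, int(round(0.15 * min(nx, ny))))
    region_angles = np.linspace(0, np.pi / 4, n_crossing_regions, endpoint=False)

    # Per WM voxel, collect fiber directions from every band that covers it.
    fibers: list[list[np.ndarray]] = [[] for _ in range(wm_idx.size)]
    for k, ang in enumerate(region_angles):
        u = np.array([np.cos(ang), np.sin(ang), 0.0])
        v = np.array([-np.sin(ang), np.cos(ang), 0.0])
        # Coordinates of WM voxels in the rotated in-plane frame.
        px = (wm_x - cx) * u[0] + (wm_y - cy) * u[1]
        py = (wm_x - cx) * v[0] + (wm_y - cy) * v[1]
        off = 0.0 if n_crossing_regions == 1 else (k - (n_crossing_regions - 1) / 2)
        in_a = np.abs(py - off) <= half_w     # band running along u
        in_b = np.abs(px + off) <= half_w     # band running along v
        for i in np.nonzero(in_a)[0]:
            fibers[i].append(u)
        for i in np.nonzero(in_b)[0]:
            fibers[i].append(v)
    # Three-fiber core: the two central slices of every crossing region — a
    # spatially coherent slab, leaving the remaining overlap with two fibers.
    ez = np.array([0.0, 0.0, 1.0])
    for i in range(wm_idx.size):
        if len(fibers[i]) >= 2 and abs(wm_z[i] - cz) <= 1.0:
            fibers[i].append(ez)
    # Background WM: single fiber along the first band direction.
    u0 = np.array([1.0, 0.0, 0.0])
    for i in range(wm_idx.size):
        if not fibers[i]:
            fibers[i].append(u0)

    frac_table = {1: [1.0], 2: [0.5, 0.5], 3: [0.35, 0.35, 0.30]}
    for i, voxel in enumerate(wm_idx):
        flist = fibers[i][:3]
        snapped = []
        seen = set()
        for d in flist:
            j, dd = _snap_to_dictionary(d, dirs)
            if j not in seen:
                seen.add(j)
                snapped.append((j, dd))
        fracs = frac_table[len(snapped)]
        pdirs = np.array([dd for _, dd in snapped])
        true_peaks[int(voxel)] = (pdirs, np.array(fracs))
        for (j, _), f in zip(snapped, fracs):
            X[j, voxel] = f

    gm_idx = np.nonzero(gm.ravel())[0]
    csf_idx = np.nonzero(csf.ravel())[0]
    X[n, gm_idx] = 1.0
    X[n + 1, csf_idx] = 1.0

    # Smooth s0 with mean about 1 over the brain.
    s0 = np.where(brain, 0.8 + 0.4 * np.exp(-(rho**2)), 0.0)
    s0 = s0 / s0[brain].mean()

    return Phantom(
        shape=shape,
        tissue_maps={"wm": wm, "gm": gm, "csf": csf},
        true_fod=X,
        true_peaks=true_peaks,
        s0=s0,
        direction_set=dirs,
    )


def simulate_coils(shape: tuple, C: int = DEFAULT_N_COILS, seed: int = 0) -> CoilProfiles:
    """Smooth complex coil maps: Gaussian magnitude lobes placed around the
    volume times a low-order polynomial phase.  Deterministic per seed."""
    if C < 1:
        raise ValueError("C must be >= 1")
    shape = tuple(int(s) for s in shape)
    nx, ny, nz = shape
    rng = np.random.default_rng(seed)
    xx, yy, zz = np.meshgrid(
        np.linspace(-1, 1, nx), np.linspace(-1, 1, ny), np.linspace(-1, 1, nz),
        indexing="ij",
    )
    maps = np.empty((C,) + shape, dtype=complex)
    for c in range(C):
        ang = 2 * np.pi * c / C + rng.normal(0, 0.1)
        ccx, ccy = 1.3 * np.cos(ang), 1.3 * np.sin(ang)
        sig = 1.0 + 0.2 * rng.normal()
        mag = np.exp(-(((xx - ccx) ** 2 + (yy - ccy) ** 2 + zz**2) / (2 * sig**2)))
        a = rng.normal(0, 0.5, size=3)
        b = rng.normal(0, 0.3, size=3)
        phase = a[0] * xx + a[1] * yy + a[2] * zz + b[0] * xx * yy + b[1] * xx**2 + b[2] * yy**2
        maps[c] = mag * np.exp(1j * phase)
    return CoilProfiles(maps=maps)


def simulate_phase(
    shape: tuple,
    q: int,
    c: int,
    max_shift_lines: float = DEFAULT_MAX_SHIFT_LINES,
    inhomogeneity_amplitude: float = 0.3,
    seed: int = 0,
) -> np.ndarray:
    """Unit-modulus phase volume for gradient q and coil c.

    The motion surrogate is a linear phase ramp along the phase-encoding
    axis whose induced k-space shift is drawn uniformly within
    ``max_shift_lines`` lines; the b=0 gradient (q=0) gets no motion ramp.
    A smooth low-frequency inhomogeneity term of the given amplitude
    (radians) is added for every gradient.
    """
    if max_shift_lines < 0:
        raise ValueError("max_shift_lines must be >= 0")
    shape = tuple(int(s) for s in shape)
    rng = np.random.default_rng((int(seed) * 100003 + q * 131 + c) % (2**32))
    n_pe = shape[PHASE_AXIS]
    theta = np.zeros(shape, dtype=float)
    if q != 0 and max_shift_lines > 0:
        shift = rng.uniform(-max_shift_lines, max_shift_lines)
        pe = np.arange(n_pe) - n_pe // 2
        ramp = 2 * np.pi * shift * pe / n_pe
        sl = [None, None, None]
        sl[PHASE_AXIS] = slice(None)
        theta = theta + ramp[tuple(
            slice(None) if ax == PHASE_AXIS else None for ax in range(3)
        )]
    if inhomogeneity_amplitude > 0:
        xx, yy, zz = np.meshgrid(
            np.linspace(-1, 1, shape[0]),
            np.linspace(-1, 1, shape[1]),
            np.linspace(-1, 1, shape[2]),
            indexing="ij",
        )
        a = rng.normal(0, 1, size=6)
        smooth = (
            a[0] * xx + a[1] * yy + a[2] * zz
            + a[3] * xx * yy + a[4] * np.cos(np.pi * xx) + a[5] * np.cos(np.pi * yy)
        )
        theta = theta + inhomogeneity_amplitude * smooth
    return np.exp(1j * theta)


def make_phase_maps(
    shape: tuple,
    M: int,
    C: int,
    max_shift_lines: float = DEFAULT_MAX_SHIFT_LINES,
    inhomogeneity_amplitude: float = 0.3,
    seed: int = 0,
) -> PhaseMaps:
    maps = np.empty((M, C) + tuple(shape), dtype=complex)
    for q in range(M):
        for c in range(C):
            maps[q, c] = simulate_phase(
                shape, q, c, max_shift_lines, inhomogeneity_amplitude, seed
            )
    return PhaseMaps(maps=maps)


def kspace_shift_lines(phase_volume: np.ndarray) -> float:
    """Empirical k-space centroid shift (in phase-encoding lines) that a
    unit-modulus phase volume imparts to a spatially constant object.

    A constant object's spectrum is a spike at DC; multiplying by the phase
    translates the spike along the phase-encoding axis.  The shift is read
    off by localizing the spectral peak on a 16x zero-padded grid with
    parabolic interpolation (bias below 1e-4 lines).
    """
    vol = np.asarray(phase_volume)
    # Collapse the non-phase-encoding axes (the ramp varies only along the
    # PE axis), zero-pad 16x for a finely sampled spectrum, and localize the
    # spectral peak with parabolic interpolation.
    line = vol.mean(axis=tuple(ax for ax in range(3) if ax != PHASE_AXIS))
    n = line.size
    pad = 16
    m = n * pad
    x = np.zeros(m, dtype=complex)
    x[(m - n) // 2: (m + n) // 2] = line
    khat = np.fft.fftshift(np.fft.fft(np.fft.ifftshift(x)))
    prof = np.abs(khat) ** 2
    i0 = int(np.argmax(prof))
    if 0 < i0 < m - 1:
        ym, y0, yp = prof[i0 - 1], prof[i0], prof[i0 + 1]
        denom = ym - 2 * y0 + yp
        d = 0.5 * (ym - yp) / denom if denom != 0 else 0.0
    else:
        d = 0.0
    return float((i0 + d - m // 2) / pad)


def simulate_acquisition(
    phantom: Phantom,
    dictionary: Dictionary,
    scheme: GradientScheme,
    masks: list[SamplingMask],
    coils: CoilProfiles,
    phases: PhaseMaps,
    snr: float = DEFAULT_SNR,
    seed: int = 0,
):
    """Noisy under-sampled multi-coil k-space data of the phantom.

    Returns ``(kdata, model)`` where ``model`` is the exact acquisition
    model used (ground-truth s0, coils, phases) and ``kdata`` holds
    Y(q,c) = A_{q,c}(X_true) + eta with eta complex i.i.d. Gaussian of
    standard deviation mean(s0)/snr per real/imaginary part.  ``snr`` may be
    ``np.inf`` for noiseless data.
    """
    from .forward_model import AcquisitionModel, apply_A

    if dictionary.M != scheme.M or len(masks) != scheme.M:
        raise ValueError("dictionary, scheme and masks must agree on M")
    if phases.maps.shape[:2] != (scheme.M, coils.C):
        raise ValueError("phase maps must be indexed (M, C)")
    if not snr > 0:
        raise ValueError("snr must be positive (np.inf for noiseless)")
    model = AcquisitionModel(
        dictionary=dictionary,
        s0=phantom.s0,
        coils=coils,
        phases=phases,
        masks=masks,
        grid_shape=phantom.shape,
    )
    kdata = apply_A(phantom.true_fod, model)
    if np.isfinite(snr):
        sigma = phantom.mean_s0 / snr
        rng = np.random.default_rng(seed)
        for q in range(scheme.M):
            s = kdata.samples[q]
            noise = rng.normal(0, sigma, size=s.shape) + 1j * rng.normal(
                0, sigma, size=s.shape
            )
            kdata.samples[q] = s + noise
    return kdata, model
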