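"""q-space schemes and two-phase EPI-style Cartesian k-space masks.

k-space is under-sampled per diffusion gradient by fully sampling a central
band of phase-encoding lines (needed for phase calibration) while regularly
skipping lines at the periphery — the pattern a two-phase uniform EPI readout
would produce.  The same 2D pattern is applied to every slice.  The mask for
the b=0 gradient (index 0) always retains the whole grid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dictionary import DirectionSet, GradientScheme, sample_hemisphere

__all__ = [
    "SamplingMask",
    "MultiShellSpec",
    "DEFAULT_MULTISHELL",
    "qspace_single_shell",
    "qspace_subset",
    "qspace_multishell",
    "kmask_two_phase",
    "undersampling_factor",
    "solve_target_factor",
    "masks_for_scheme",
]

# Phase-encoding lines run along axis 0; axis 1 is the fully sampled readout
# direction; axis 2 indexes slices (identical pattern on every slice).
PHASE_AXIS = 0


@dataclass(frozen=True)
class SamplingMask:
    """Retained phase-encoding lines of a Cartesian k-space grid."""

    grid_shape: tuple
    kept_lines: np.ndarray          # sorted int line indices along PHASE_AXIS
    gradient_index: int
    center_lines: np.ndarray        # the fully sampled central band

    @property
    def K(self) -> int:
        ny, nz = self.grid_shape[1], self.grid_shape[2]
        return int(self.kept_lines.size) * ny * nz

    @property
    def N(self) -> int:
        return int(np.prod(self.grid_shape))

    def as_array(self) -> np.ndarray:
        """Dense boolean mask over the 3D grid."""
        m = np.zeros(self.grid_shape, dtype=bool)
        m[self.kept_lines] = True
        return m


@dataclass(frozen=True)
class MultiShellSpec:
    shell_bvals: tuple
    shell_counts: tuple
    center_shell: int

    def __post_init__(self) -> None:
        if len(self.shell_bvals) != len(self.shell_counts):
            raise ValueError("shell_bvals and shell_counts length mismatch")
        if any(c < 0 for c in self.shell_counts):
            raise ValueError("shell counts must be nonnegative")
        if list(self.shell_bvals) != sorted(self.shell_bvals):
            raise ValueError("shells must be sorted by b-value")

    @property
    def total(self) -> int:
        return int(sum(self.shell_counts))


# Eight-shell scheme used for multi-shell experiments: b from 550 to
# 4800 s/mm^2, preferential sampling centered on shell 5 (b=2650).  The
# printed per-shell counts sum to 59.
DEFAULT_MULTISHELL = MultiShellSpec(
    shell_bvals=(550, 1050, 1600, 2150, 2650, 3200, 4250, 4800),
    shell_counts=(3, 6, 4, 3, 12, 12, 6, 13),
    center_shell=4,
)


def qspace_single_shell(M: int, b: float = 1000.0, seed: int = 0) -> GradientScheme:
    """Single-shell scheme: one leading b=0 entry plus M uniform directions."""
    if M < 1:
        raise ValueError("M must be >= 1")
    dirs = sample_hemisphere(M, seed=seed)
    bvals = np.concatenate([[0.0], np.full(M, float(b))])
    bvecs = np.vstack([[0.0, 0.0, 0.0], dirs.directions])
    return GradientScheme(bvals=bvals, bvecs=bvecs)


def qspace_subset(scheme: GradientScheme, M_sub: int) -> GradientScheme:
    """Nested uniform subset of a single-shell scheme.

    Keeps the b=0 entry and every roughly (M/M_sub)-th diffusion entry, so
    subsets of increasing size are nested in the index ordering.
    """
    dw = np.nonzero(scheme.bvals > 0)[0]
    if not 1 <= M_sub <= dw.size:
        raise ValueError("subset size out of range")
    pick = dw[np.floor(np.arange(M_sub) * dw.size / M_sub).astype(int)]
    keep = np.concatenate([[0], pick])
    return GradientScheme(bvals=scheme.bvals[keep], bvecs=scheme.bvecs[keep])


def qspace_multishell(
    spec: MultiShellSpec = DEFAULT_MULTISHELL,
    subset_size: int | None = None,
    seed: int = 0,
    shell_sigma: float = 1.5,
) -> GradientScheme:
    """Multi-shell scheme with Gaussian shell-weighted subset selection.

    The full scheme allocates ``shell_counts[s]`` quasi-uniform directions on
    each shell.  When ``subset_size`` is given, points are drawn without
    replacement with per-point probability proportional to a Gaussian in the
    shell index centered on ``center_shell`` — shells near the center
    (b around 2000-3000 s/mm^2 for the default) are sampled preferentially.
    """
    rng = np.random.default_rng(seed)
    bvals_list = [0.0]
    bvecs_list = [np.zeros(3)]
    shell_of_point = []
    for s, (b, cnt) in enumerate(zip(spec.shell_bvals, spec.shell_counts)):
        if cnt == 0:
            continue
        dirs = sample_hemisphere(cnt, seed=1000 + s)
        for d in dirs.directions:
            bvals_list.append(float(b))
            bvecs_list.append(d)
            shell_of_point.append(s)
    bvals = np.array(bvals_list)
    bvecs = np.vstack(bvecs_list)
    total = len(shell_of_point)
    if subset_size is None or subset_size == total:
        return GradientScheme(bvals=bvals, bvecs=bvecs)
    if subset_size > total:
        raise ValueError(f"subset_size {subset_size} exceeds total {total}")
    shell_idx = np.asarray(shell_of_point)
    w = np.exp(-0.5 * ((shell_idx - spec.center_shell) / shell_sigma) ** 2)
    p = w / w.sum()
    pick = rng.choice(total, size=subset_size, replace=False, p=p)
    keep = np.concatenate([[0], 1 + np.sort(pick)])
    return GradientScheme(bvals=bvals[keep], bvecs=bvecs[keep])


def kmask_two_phase(
    grid_shape: tuple,
    center_fraction: float = 1.0 / 8.0,
    skip: int = 1,
    gradient_index: int = 1,
    phase_offset: int | None = None,
    seed: int = 0,
) -> SamplingMask:
    """Two-phase mask: full central band, every ``skip``-th peripheral line.

    The central band has ``max(4, round(center_fraction * n_lines))`` lines
    (clipped to the grid), centered on the DC line ``n_lines // 2``.  The
    peripheral lines keep every ``skip``-th line starting from a per-gradient
    offset (seeded if not given).  ``gradient_index == 0`` (the b=0 volume)
    always returns the full mask.
    """
    if not 0 < center_fraction <= 1:
        raise ValueError("center_fraction must lie in (0, 1]")
    if skip < 1:
        raise ValueError("skip must be >= 1")
    n_lines = int(grid_shape[PHASE_AXIS])
    n_center = min(n_lines, max(4, int(round(center_fraction * n_lines))))
    if n_center < 1:
        raise ValueError("mask must retain a fully sampled central band")
    c0 = n_lines // 2 - n_center // 2
    center = np.arange(c0, min(n_lines, c0 + n_center))
    if gradient_index == 0 or skip == 1:
        kept = np.arange(n_lines)
        if gradient_index == 0:
            center = kept
        return SamplingMask(tuple(grid_shape), kept, gradient_index, center)
    if phase_offset is None:
        rng = np.random.default_rng((int(seed) * 7919 + gradient_index) % (2**32))
        phase_offset = int(rng.integers(skip))
    periph = np.arange(phase_offset % skip, n_lines, skip)
    kept = np.union1d(center, periph)
    return SamplingMask(tuple(grid_shape), kept, gradient_index, center)


def undersampling_factor(mask: SamplingMask) -> float:
    """N/K: grid points over retained samples."""
    if mask.K == 0:
        raise ValueError("mask retains no samples")
    return mask.N / mask.K


def solve_target_factor(
    grid_shape: tuple, target: float, tol: float = 0.10
) -> tuple[float, int, list]:
    """Find (center_fraction, skip, allowed_offsets) whose under-sampling
    factor lands within ``tol`` of ``target``.

    Searches skips from densest periphery upward and, per skip, center
    widths from widest downward; the first combination for which some
    peripheral phase offset lands within the tolerance wins, and every
    offset that does is returned (per-gradient offsets are later drawn from
    this set).  Raises if no combination lands within the tolerance.
    """
    if target < 1:
        raise ValueError("target factor must be >= 1")
    n_lines = int(grid_shape[PHASE_AXIS])
    if target == 1.0:
        return 1.0, 1, [0]
    for skip in range(2, n_lines + 1):
        for n_center in range(n_lines, 3, -1):
            c0 = n_lines // 2 - n_center // 2
            c1 = min(n_lines, c0 + n_center)
            allowed = []
            for off in range(skip):
                periph = np.arange(off, n_lines, skip)
                outside = int(np.count_nonzero((periph < c0) | (periph >= c1)))
                f = n_lines / (n_center + outside)
                if abs(f - target) / target <= tol:
                    allowed.append(off)
            if allowed:
                return n_center / n_lines, skip, allowed
    raise ValueError(f"no two-phase mask reaches factor {target} on "
                     f"{n_lines} lines within {tol:.0%}")


def masks_for_scheme(
    scheme: GradientScheme,
    grid_shape: tuple,
    factor: float = 1.0,
    seed: int = 0,
) -> list[SamplingMask]:
    """One mask per gradient: full for b=0, two-phase at ``factor`` otherwise.

    Peripheral phase offsets differ per gradient (seeded), the central band
    is identical for all gradients.
    """
    if factor <= 1.0:
        return [
            kmask_two_phase(grid_shape, 1.0, 1, gradient_index=q)
            for q in range(scheme.M)
        ]
    frac, skip, allowed = solve_target_factor(grid_shape, factor)
    rng = np.random.default_rng((int(seed) + 4241) % (2**32))
    return [
        kmask_two_phase(
            grid_shape, frac, skip, gradient_index=q,
            phase_offset=int(allowed[rng.integers(len(allowed))]),
        )
        for q in range(scheme.M)
    ]
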