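"""Peak extraction from FOD columns and fiber-level evaluation metrics.

A peak is a dictionary direction whose coefficient dominates every
coefficient within its 30-degree cone; peaks below 20% of the voxel maximum
are suppressed as spurious, at most eight peaks are kept per voxel, and
retained peaks are pairwise separated by more than the extraction cone.

Evaluation compares estimated against true peak fields voxel by voxel: a
voxel is a success when the estimated fiber count is correct and every
greedily matched pair lies within a 30-degree tolerance cone.  The mean
angular error averages, over all true fibers, the axial angle to the closest
estimated fiber (90 degrees when a voxel has no estimated peak); false
positives/negatives count unmatched estimated/true fibers per voxel.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dictionary import DirectionSet, axial_angle_deg

__all__ = [
    "PeakSet",
    "EvalReport",
    "extract_peaks",
    "extract_peak_field",
    "angular_error",
    "evaluate",
]

EXTRACTION_CONE_DEG = 30.0
MAX_PEAKS = 8
REL_THRESHOLD = 0.2
SUCCESS_CONE_DEG = 30.0


@dataclass
class PeakSet:
    """Per-voxel peaks ordered by amplitude descending."""

    directions: np.ndarray       # (k, 3) unit vectors
    amplitudes: np.ndarray       # (k,)

    @property
    def count(self) -> int:
        return int(self.amplitudes.size)


@dataclass
class EvalReport:
    SR: float
    mean_angular_error: float
    FP: float
    FN: float
    per_voxel: dict = field(default_factory=dict)  # maps keyed by flat index

    def as_dict(self) -> dict:
        return {
            "SR": self.SR,
            "mean_angular_error_deg": self.mean_angular_error,
            "FP": self.FP,
            "FN": self.FN,
        }


def extract_peaks(
    fod_column: np.ndarray,
    dirs: DirectionSet,
    cone_degrees: float = EXTRACTION_CONE_DEG,
    max_peaks: int = MAX_PEAKS,
    rel_thresh: float = REL_THRESHOLD,
    cone_adjacency: np.ndarray | None = None,
) -> PeakSet:
    """Local-maximum peak extraction on the discretized hemisphere.

    ``cone_adjacency`` may carry a precomputed boolean (n, n) cone-membership
    matrix to amortize the all-pairs angle computation across voxels.
    """
    x = np.asarray(fod_column, dtype=float)
    if (x < 0).any():
        raise ValueError("FOD coefficients must be nonnegative")
    if x.size != dirs.n:
        raise ValueError("column length must match the direction count")
    empty = PeakSet(np.empty((0, 3)), np.empty(0))
    xmax = x.max() if x.size else 0.0
    if xmax <= 0:
        return empty
    if cone_adjacency is None:
        d = dirs.directions
        ang = axial_angle_deg(d[:, None, :], d[None, :, :])
        cone_adjacency = ang <= cone_degrees
    # Candidate: coefficient >= every coefficient inside its own cone.
    is_cand = np.array(
        [x[i] > 0 and x[i] >= x[cone_adjacency[i]].max() for i in range(x.size)]
    )
    is_cand &= x >= rel_thresh * xmax
    cand = np.nonzero(is_cand)[0]
    if cand.size == 0:
        return empty
    # Greedy by amplitude, ties broken by direction index (stable sort).
    order = cand[np.argsort(-x[cand], kind="stable")]
    chosen: list[int] = []
    for i in order:
        if len(chosen) >= max_peaks:
            break
        if all(not cone_adjacency[i, j] for j in chosen):
            chosen.append(int(i))
    return PeakSet(
        directions=dirs.directions[chosen].copy(),
        amplitudes=x[chosen].copy(),
    )


def extract_peak_field(
    S1: np.ndarray,
    wm_idx: np.ndarray,
    dirs: DirectionSet,
    cone_degrees: float = EXTRACTION_CONE_DEG,
    max_peaks: int = MAX_PEAKS,
    rel_thresh: float = REL_THRESHOLD,
) -> dict:
    """Peak sets for every WM voxel of an (n, N1) coefficient block."""
    d = dirs.directions
    ang = axial_angle_deg(d[:, None, :], d[None, :, :])
    adjacency = ang <= cone_degrees
    return {
        int(v): extract_peaks(
            S1[:, i], dirs, cone_degrees, max_peaks, rel_thresh, adjacency
        )
        for i, v in enumerate(wm_idx)
    }


def angular_error(d_true: np.ndarray, d_est: np.ndarray) -> float:
    """Axial angle between two fiber directions, in degrees [0, 90]."""
    d_true = np.asarray(d_true, dtype=float)
    d_est = np.asarray(d_est, dtype=float)
    for v in (d_true, d_est):
        if abs(np.linalg.norm(v) - 1.0) > 1e-8:
            raise ValueError("directions must be unit vectors")
    return float(axial_angle_deg(d_true, d_est))


def _match_voxel(est: PeakSet, true: PeakSet, tol: float):
    """Greedy one-to-one matching, smallest angle first, within tol."""
    ne, nt = est.count, true.count
    if ne and nt:
        ang = axial_angle_deg(
            true.directions[:, None, :], est.directions[None, :, :]
        )
    else:
        ang = np.empty((nt, ne))
    pairs = sorted(
        ((ang[i, j], i, j) for i in range(nt) for j in range(ne)),
        key=lambda t: (t[0], t[1], t[2]),
    )
    used_t: set = set()
    used_e: set = set()
    matched = []
    for a, i, j in pairs:
        if a > tol:
            break
        if i in used_t or j in used_e:
            continue
        used_t.add(i)
        used_e.add(j)
        matched.append((i, j, a))
    fp = ne - len(used_e)
    fn = nt - len(used_t)
    success = (ne == nt) and (fp == 0) and (fn == 0)
    # Mean-angular-error contributions: closest estimated fiber per true
    # fiber regardless of matching; 90 degrees when nothing was estimated.
    if ne == 0:
        errs = [90.0] * nt
    else:
        errs = [float(ang[i].min()) for i in range(nt)]
    return success, fp, fn, errs


def evaluate(
    est_field: dict,
    truth_field: dict,
    tol_degrees: float = SUCCESS_CONE_DEG,
) -> EvalReport:
    """Voxel-wise comparison of estimated and true peak fields.

    Both fields map flat voxel indices to PeakSets; evaluation runs over the
    truth's voxels (the white-matter support of the phantom).
    """
    if not truth_field:
        raise ValueError("truth field is empty")
    succ_map: dict = {}
    fp_map: dict = {}
    fn_map: dict = {}
    err_map: dict = {}
    all_errs: list = []
    empty = PeakSet(np.empty((0, 3)), np.empty(0))
    for v, true_ps in truth_field.items():
        est_ps = est_field.get(v, empty)
        success, fp, fn, errs = _match_voxel(est_ps, true_ps, tol_degrees)
        succ_map[v] = float(success)
        fp_map[v] = fp
        fn_map[v] = fn
        err_map[v] = float(np.mean(errs)) if errs else 0.0
        all_errs.extend(errs)
    nv = len(truth_field)
    return EvalReport(
        SR=float(np.mean(list(succ_map.values()))),
        mean_angular_error=float(np.mean(all_errs)) if all_errs else 0.0,
        FP=float(np.sum(list(fp_map.values())) / nv),
        FN=float(np.sum(list(fn_map.values())) / nv),
        per_voxel={
            "success": succ_map,
            "fp": fp_map,
            "fn": fn_map,
            "angular_error": err_map,
        },
    )
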