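"""Readers and writers: NIfTI volumes, FSL bval/bvec tables, and the HDF5
acquisition container.

Container layout (schema version 1):

    /kspace/q{q}/c{c}    complex masked samples of gradient q, coil c
    /masks/q{q}          boolean 3D grid
    /coils/c{c}          complex coil sensitivity volume
    /phases/q{q}_c{c}    complex unit-modulus phase volume
    /s0                  b=0 volume
    /tissue/{wm,gm,csf}  boolean masks (optional)
    /scheme/{bvals,bvecs}
    attrs: schema_version, snr, seed, factor, grid_shape

k-space is stored unshifted with DC at the grid center (attr ``dc_centered``).
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import nibabel as nib
import numpy as np

from .dictionary import GradientScheme
from .phantom import CoilProfiles, PhaseMaps
from .sampling import SamplingMask

__all__ = [
    "save_volume",
    "load_volume",
    "write_bvals_bvecs",
    "read_bvals_bvecs",
    "write_acquisition",
    "read_acquisition",
    "write_report",
]

SCHEMA_VERSION = 1
_DEFAULT_AFFINE = np.eye(4)


def save_volume(data: np.ndarray, path, affine: np.ndarray | None = None) -> None:
    """Write a 3D/4D array as NIfTI-1 (explicit affine, default identity)."""
    img = nib.Nifti1Image(
        np.asarray(data), _DEFAULT_AFFINE if affine is None else affine
    )
    nib.save(img, str(path))


def load_volume(path) -> np.ndarray:
    return np.asarray(nib.load(str(path)).dataobj)


def write_bvals_bvecs(scheme: GradientScheme, bval_path, bvec_path) -> None:
    """FSL dialect: bvals on one line; bvecs as 3 rows of M columns."""
    with open(bval_path, "w") as f:
        f.write(" ".join(f"{b:g}" for b in scheme.bvals) + "\n")
    with open(bvec_path, "w") as f:
        for row in scheme.bvecs.T:
            f.write(" ".join(f"{x:.10g}" for x in row) + "\n")


def read_bvals_bvecs(bval_path, bvec_path) -> GradientScheme:
    try:
        bvals = np.loadtxt(bval_path, ndmin=1)
    except ValueError as e:
        raise ValueError(f"malformed bval file {bval_path}: {e}") from e
    try:
        bvecs = np.loadtxt(bvec_path, ndmin=2)
    except ValueError as e:
        raise ValueError(f"malformed bvec file {bvec_path}: {e}") from e
    if bvecs.shape[0] != 3:
        raise ValueError(
            f"bvec file {bvec_path}: expected 3 rows x M columns, got "
            f"{bvecs.shape}"
        )
    if bvecs.shape[1] != bvals.size:
        raise ValueError("bval/bvec column counts disagree")
    return GradientScheme(bvals=bvals, bvecs=bvecs.T)


def write_acquisition(
    path,
    kdata,
    masks: list,
    coils: CoilProfiles,
    phases: PhaseMaps,
    s0: np.ndarray,
    scheme: GradientScheme,
    tissue_maps: dict | None = None,
    attrs: dict | None = None,
) -> None:
    grid_shape = tuple(s0.shape)
    with h5py.File(path, "w") as f:
        f.attrs["schema_version"] = SCHEMA_VERSION
        f.attrs["grid_shape"] = grid_shape
        f.attrs["dc_centered"] = True
        for k, v in (attrs or {}).items():
            f.attrs[k] = v
        gk = f.create_group("kspace")
        for q in range(scheme.M):
            gq = gk.create_group(f"q{q}")
            for c in range(coils.C):
                gq.create_dataset(f"c{c}", data=kdata.samples[q][c])
        gm = f.create_group("masks")
        for q, m in enumerate(masks):
            d = gm.create_dataset(f"q{q}", data=m.as_array())
            d.attrs["kept_lines"] = m.kept_lines
            d.attrs["center_lines"] = m.center_lines
        gc = f.create_group("coils")
        for c in range(coils.C):
            gc.create_dataset(f"c{c}", data=coils.maps[c])
        gp = f.create_group("phases")
        for q in range(scheme.M):
            for c in range(coils.C):
                gp.create_dataset(f"q{q}_c{c}", data=phases.maps[q, c])
        f.create_dataset("s0", data=s0)
        gs = f.create_group("scheme")
        gs.create_dataset("bvals", data=scheme.bvals)
        gs.create_dataset("bvecs", data=scheme.bvecs)
        if tissue_maps is not None:
            gt = f.create_group("tissue")
            for name in ("wm", "gm", "csf"):
                gt.create_dataset(name, data=tissue_maps[name])


def _require(f, key: str):
    if key not in f:
        raise KeyError(f"acquisition container is missing '/{key}'")
    return f[key]


def read_acquisition(path) -> dict:
    """Load a container back into in-memory objects.

    Returns a dict with keys kdata (KSpaceData), masks, coils, phases, s0,
    scheme, tissue_maps (or None) and attrs.
    """
    from .forward_model import KSpaceData

    with h5py.File(path, "r") as f:
        for key in ("kspace", "masks", "coils", "phases", "s0", "scheme"):
            _require(f, key)
        grid_shape = tuple(int(x) for x in f.attrs["grid_shape"])
        scheme = GradientScheme(
            bvals=f["scheme/bvals"][()], bvecs=f["scheme/bvecs"][()]
        )
        M = scheme.M
        C = len(f["coils"])
        masks = []
        for q in range(M):
            d = f["masks"][f"q{q}"]
            masks.append(
                SamplingMask(
                    grid_shape=grid_shape,
                    kept_lines=np.asarray(d.attrs["kept_lines"]),
                    gradient_index=q,
                    center_lines=np.asarray(d.attrs["center_lines"]),
                )
            )
        samples = []
        for q in range(M):
            stack = [f["kspace"][f"q{q}"][f"c{c}"][()] for c in range(C)]
            samples.append(np.asarray(stack))
        kdata = KSpaceData(samples)
        coils = CoilProfiles(
            maps=np.asarray([f["coils"][f"c{c}"][()] for c in range(C)])
        )
        pm = np.empty((M, C) + grid_shape, dtype=complex)
        for q in range(M):
            for c in range(C):
                pm[q, c] = f["phases"][f"q{q}_c{c}"][()]
        phases = PhaseMaps(maps=pm)
        s0 = f["s0"][()]
        tissue = None
        if "tissue" in f:
            tissue = {k: f["tissue"][k][()].astype(bool) for k in ("wm", "gm", "csf")}
        attrs = dict(f.attrs)
    return {
        "kdata": kdata,
        "masks": masks,
        "coils": coils,
        "phases": phases,
        "s0": s0,
        "scheme": scheme,
        "tissue_maps": tissue,
        "attrs": attrs,
    }


def write_report(report: dict, path) -> None:
    Path(path).write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
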