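"""Readers/writers for FSL bvals/bvecs and MRtrix gradient tables.

FSL stores b-values as a single whitespace-separated row and directions as
3 rows × N columns; MRtrix uses one ``x y z b`` row per volume.  Readers
normalize non-unit vectors and treat b below 50 s/mm² as b = 0.
"""

from __future__ import annotations

import numpy as np

from .scheme import B0_THRESHOLD, GradientScheme

__all__ = ["read_fsl", "write_fsl", "read_mrtrix", "write_mrtrix"]


def _scheme_from_arrays(directions: np.ndarray, bvalues: np.ndarray) -> GradientScheme:
    bvalues = np.asarray(bvalues, dtype=float)
    directions = np.asarray(directions, dtype=float).copy()
    dw = bvalues > B0_THRESHOLD
    bvalues = np.where(dw, bvalues, 0.0)
    norms = np.linalg.norm(directions, axis=1)
    if np.any(norms[dw] < 1e-12):
        raise ValueError("zero direction on a diffusion-weighted volume")
    # vectors already unit to fixed-point precision are kept verbatim so a
    # canonical 6-decimal table round-trips bit-identically
    renorm = dw & (np.abs(norms - 1.0) > 1e-6)
    directions[renorm] /= norms[renorm][:, None]
    directions[~dw] = 0.0
    shell_id = np.zeros(len(bvalues), dtype=int)
    for k, b in enumerate(sorted(set(bvalues[dw].tolist()))):
        shell_id[bvalues == b] = k + 1
    return GradientScheme(directions=directions, bvalues=bvalues, shell_id=shell_id)


def read_fsl(bvals_path, bvecs_path) -> GradientScheme:
    bvals = np.loadtxt(bvals_path, ndmin=1)
    bvecs = np.loadtxt(bvecs_path, ndmin=2)
    if bvecs.shape[0] != 3:
        raise ValueError(f"bvecs must have 3 rows, got {bvecs.shape[0]}")
    if bvecs.shape[1] != bvals.size:
        raise ValueError("bvals and bvecs disagree on volume count")
    return _scheme_from_arrays(bvecs.T, bvals)


def write_fsl(scheme: GradientScheme, bvals_path, bvecs_path) -> None:
    with open(bvals_path, "w") as f:
        f.write(" ".join(f"{b:.6f}" for b in scheme.bvalues) + "\n")
    with open(bvecs_path, "w") as f:
        for row in scheme.directions.T:
            f.write(" ".join(f"{x:.6f}" for x in row) + "\n")


def read_mrtrix(path) -> GradientScheme:
    table = np.loadtxt(path, ndmin=2)
    if table.shape[1] != 4:
        raise ValueError("MRtrix gradient table must have 4 columns: x y z b")
    return _scheme_from_arrays(table[:, :3], table[:, 3])


def write_mrtrix(scheme: GradientScheme, path) -> None:
    """Write an ``x y z b`` table; fixed 6-decimal output round-trips exactly."""
    with open(path, "w") as f:
        for d, b in zip(scheme.directions, scheme.bvalues):
            f.write(f"{d[0]:.6f} {d[1]:.6f} {d[2]:.6f} {b:.6f}\n")
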