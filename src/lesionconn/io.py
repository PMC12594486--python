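"""Reading and writing the standard on-disk formats.

NIfTI-1 volumes (signal map, WM/lesion masks, integer parcellation) go
through nibabel; tractograms through ``nibabel.streamlines`` (TCK and TRK,
points always exposed in world mm / RASmm); connectomes and cohort
manifests as CSV; fit reports as JSON; run configuration as YAML.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .connectome import Connectome

__all__ = ["read_volume", "write_volume", "read_tractogram",
           "write_tractogram", "read_connectome", "write_connectome",
           "write_fit_report", "RunConfig"]


def read_volume(path) -> tuple[np.ndarray, np.ndarray]:
    """Load a NIfTI volume; returns (data array, affine)."""
    img = nib.load(str(path))
    return np.asanyarray(img.dataobj), img.affine


def write_volume(data: np.ndarray, affine: np.ndarray, path) -> None:
    data = np.asarray(data)
    if data.dtype == bool:
        data = data.astype(np.uint8)
    nib.save(nib.Nifti1Image(data, affine), str(path))


def read_tractogram(path) -> list[np.ndarray]:
    """Streamlines from a TCK/TRK file, as float arrays in world mm."""
    path = Path(path)
    if path.suffix.lower() not in (".tck", ".trk"):
        raise ValueError(f"unknown tractogram extension: {path.suffix}")
    tf = nib.streamlines.load(str(path))  # applies the header transform
    return [np.asarray(s, dtype=np.float64) for s in tf.tractogram.streamlines]


def write_tractogram(streamlines, path,
                     affine: np.ndarray | None = None) -> None:
    """Save streamlines (world mm) as TCK or TRK."""
    path = Path(path)
    tractogram = nib.streamlines.Tractogram(
        [np.asarray(s, dtype=np.float32) for s in streamlines],
        affine_to_rasmm=np.eye(4))
    if path.suffix.lower() == ".tck":
        f = nib.streamlines.TckFile(tractogram)
    elif path.suffix.lower() == ".trk":
        header = nib.streamlines.TrkFile.create_empty_header()
        if affine is not None:
            header["voxel_to_rasmm"] = affine.astype(np.float32)
            header["voxel_sizes"] = np.linalg.norm(affine[:3, :3],
                                                   axis=0).astype(np.float32)
        f = nib.streamlines.TrkFile(tractogram, header=header)
    else:
        raise ValueError(f"unknown tractogram extension: {path.suffix}")
    f.save(str(path))


def write_connectome(conn: Connectome, path) -> None:
    """CSV matrix with 1-based node labels, plus a variant sidecar JSON."""
    path = Path(path)
    labels = [str(i + 1) for i in range(conn.n_nodes)]
    pd.DataFrame(conn.matrix, index=labels, columns=labels).to_csv(path)
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(json.dumps({"variant": conn.variant,
                                   "n_nodes": conn.n_nodes}))


def read_connectome(path) -> Connectome:
    path = Path(path)
    frame = pd.read_csv(path, index_col=0)
    M = frame.to_numpy(dtype=np.float64)
    variant = "standard"
    sidecar = path.with_suffix(path.suffix + ".json")
    if sidecar.exists():
        variant = json.loads(sidecar.read_text()).get("variant", "standard")
    return Connectome(matrix=M, variant=variant)  # validates symmetry


def write_fit_report(sf, path) -> None:
    """JSON summary of a fit: objective, coefficients, R summary."""
    R = sf.reduction.R
    lesioned = sf.reduction.lesion_voxels
    report = {
        "objective": sf.fit.objective,
        "n_streamlines": int(sf.fit.x.size),
        "n_lesion_voxels": int(sf.fit.xL.size),
        "x": sf.fit.x.tolist(),
        "xL": sf.fit.xL.tolist(),
        "R_lesion": [float(R.ravel()[v]) for v in lesioned],
        "c_hat": sf.weights.c_hat.tolist(),
    }
    Path(path).write_text(json.dumps(report, indent=2))


@dataclass
class RunConfig:
    """Paths and parameters for a full run, loadable from YAML."""

    signal: str = ""
    tractogram: str = ""
    lesion_mask: str | None = None
    parcellation: str = ""
    tolerance: float | None = None
    density: float = 1.0
    metrics: list[str] = field(
        default_factory=lambda: ["mean_strength", "global_efficiency",
                                 "modularity"])
    n_iterations: int = 5000
    inner_resamples: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.seed < 0:
            raise ValueError("seed must be a nonnegative integer")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.__dict__))
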