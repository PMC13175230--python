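"""4D diffusion-weighted series container and standard-format I/O.

Volumes are stored (x, y, z, volume) with a per-volume b-table; gradient
tables follow the FSL dialect (whitespace-separated ``.bval`` single line,
``.bvec`` as three rows), volumes as NIfTI via nibabel.  Phantoms carry an
identity orientation; no reorientation is performed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = ["DWISeries", "read_dwi", "write_dwi"]


@dataclass
class DWISeries:
    """A 4D DWI signal array bound to its b-table.

    ``directions`` (unit vectors per volume, zero vector for b = 0) and
    ``mask`` are optional; ``excluded`` lists volume indices dropped from
    fitting (e.g. manually identified signal voids).
    """

    data: np.ndarray                      # (x, y, z, n_volumes)
    bvalues: np.ndarray                   # (n_volumes,)
    directions: np.ndarray | None = None  # (n_volumes, 3)
    mask: np.ndarray | None = None        # (x, y, z) boolean
    excluded: list[int] = field(default_factory=list)
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.bvalues = np.atleast_1d(np.asarray(self.bvalues, dtype=float))
        if self.data.ndim != 4:
            raise ValueError(f"data must be 4D (x, y, z, volume); got {self.data.ndim}D")
        nvol = self.data.shape[3]
        if self.bvalues.size != nvol:
            raise ValueError(
                f"b-table length {self.bvalues.size} does not match "
                f"volume count {nvol}"
            )
        if self.directions is not None:
            self.directions = np.asarray(self.directions, dtype=float)
            if self.directions.shape != (nvol, 3):
                raise ValueError(
                    f"directions must be ({nvol}, 3); got {self.directions.shape}"
                )
        if self.mask is not None:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.data.shape[:3]:
                raise ValueError("mask shape must match the spatial grid")
        bad = [i for i in self.excluded if not 0 <= i < nvol]
        if bad:
            raise ValueError(f"excluded volume indices out of range: {bad}")
        if (self.data < 0).any():
            raise ValueError("signals must be >= 0")

    @property
    def n_volumes(self) -> int:
        return self.data.shape[3]

    def kept_indices(self) -> np.ndarray:
        return np.array([i for i in range(self.n_volumes) if i not in set(self.excluded)])


def write_dwi(series: DWISeries, stem: str | Path, sidecar: bool = True) -> dict[str, Path]:
    """Write NIfTI + FSL .bval/.bvec (+ BIDS-style JSON sidecar).

    ``stem`` is the path without extension; returns the written paths.
    """
    stem = Path(stem)
    stem.parent.mkdir(parents=True, exist_ok=True)
    affine = np.diag(list(series.voxel_size) + [1.0])
    img = nib.Nifti1Image(series.data.astype(np.float32), affine)
    img.header.set_zooms(tuple(series.voxel_size) + (1.0,))
    paths = {"nii": stem.with_suffix(".nii.gz")}
    nib.save(img, paths["nii"])

    paths["bval"] = stem.with_suffix(".bval")
    paths["bval"].write_text(
        " ".join(format(b, "g") for b in series.bvalues) + "\n"
    )
    bvec = (series.directions if series.directions is not None
            else np.zeros((series.n_volumes, 3)))
    paths["bvec"] = stem.with_suffix(".bvec")
    paths["bvec"].write_text(
        "\n".join(" ".join(format(v, "g") for v in row) for row in bvec.T) + "\n"
    )
    if series.mask is not None:
        paths["mask"] = stem.parent / (stem.name + "_mask.nii.gz")
        nib.save(nib.Nifti1Image(series.mask.astype(np.uint8), affine), paths["mask"])
    if sidecar:
        paths["json"] = stem.with_suffix(".json")
        paths["json"].write_text(json.dumps({
            "bvalues": series.bvalues.tolist(),
            "excluded_volumes": list(series.excluded),
            "voxel_size_mm": list(series.voxel_size),
        }, indent=2))
    return paths


def read_dwi(
    nii_path: str | Path,
    bval_path: str | Path | None = None,
    bvec_path: str | Path | None = None,
    mask_path: str | Path | None = None,
) -> DWISeries:
    """Read a 4D NIfTI with FSL-style .bval/.bvec into a :class:`DWISeries`.

    When not given, sidecar paths are derived from the NIfTI stem.  The
    b-table length must match the number of volumes.
    """
    nii_path = Path(nii_path)
    stem = nii_path.with_suffix("").with_suffix("") if nii_path.name.endswith(".nii.gz") \
        else nii_path.with_suffix("")
    bval_path = Path(bval_path) if bval_path else stem.with_suffix(".bval")
    bvec_path = Path(bvec_path) if bvec_path else stem.with_suffix(".bvec")

    img = nib.load(nii_path)
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim == 3:
        data = data[..., None]
    bvals = np.loadtxt(bval_path, ndmin=1, dtype=float).ravel()
    if bvals.size != data.shape[3]:
        raise ValueError(
            f"b-table length {bvals.size} does not match volume count {data.shape[3]}"
        )
    directions = None
    if bvec_path.exists():
        bvec = np.loadtxt(bvec_path, ndmin=2, dtype=float)
        if bvec.shape != (3, data.shape[3]):
            raise ValueError(
                f".bvec must be 3 rows x {data.shape[3]} columns; got {bvec.shape}"
            )
        directions = bvec.T
    mask = None
    if mask_path is not None:
        mask = np.asarray(nib.load(mask_path).dataobj) > 0
    zooms = img.header.get_zooms()[:3]
    excluded: list[int] = []
    sidecar = stem.with_suffix(".json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        excluded = list(meta.get("excluded_volumes", []))
    return DWISeries(
        data=data, bvalues=bvals, directions=directions, mask=mask,
        excluded=excluded, voxel_size=tuple(float(z) for z in zooms),
    )
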