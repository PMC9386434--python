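"""In-memory 4-D BOLD session container, acquisition geometry, rigid transforms.

A :class:`Session4D` holds one subject's volume time series on a regular
voxel grid together with the acquisition geometry (TR, voxel sizes, slice
gap) and a provenance dictionary that downstream stages append to
(simulation ground truth, realignment parameters, exclusion flags).

Rigid-body resampling is implemented once here and reused by motion
injection and by realignment, so that the two are exact inverses up to
interpolation error.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np
from scipy import ndimage


@dataclass(frozen=True)
class AcquisitionGeometry:
    """EPI acquisition geometry.

    Defaults follow a 16-minute infant protocol: 320 volumes at TR 3 s,
    24 near-axial slices 4.0 mm thick with a 2.0 mm gap, 3.5 x 3.5 mm
    in-plane.  ``grid_shape`` controls only the simulated matrix size;
    voxel spacing metadata is independent of it.
    """

    n_vols: int = 320
    tr_s: float = 3.0
    grid_shape: tuple = (24, 24, 24)
    voxel_mm: tuple = (3.5, 3.5, 4.0)
    slice_gap_mm: float = 2.0

    def __post_init__(self):
        if self.n_vols <= 0 or self.tr_s <= 0:
            raise ValueError("n_vols and tr_s must be positive")
        if any(v <= 0 for v in self.voxel_mm) or self.slice_gap_mm < 0:
            raise ValueError("voxel sizes must be positive, gap non-negative")

    @property
    def spacing_mm(self) -> np.ndarray:
        """Centre-to-centre voxel spacing (slice gap added along z)."""
        return np.array(
            [self.voxel_mm[0], self.voxel_mm[1], self.voxel_mm[2] + self.slice_gap_mm]
        )

    @property
    def frame_times_s(self) -> np.ndarray:
        return np.arange(self.n_vols) * self.tr_s

    @property
    def duration_s(self) -> float:
        return self.n_vols * self.tr_s

    def affine(self) -> np.ndarray:
        aff = np.diag([*self.spacing_mm, 1.0])
        aff[:3, 3] = -self.spacing_mm * (np.array(self.grid_shape) - 1) / 2.0
        return aff


@dataclass
class Session4D:
    """One subject's BOLD time series: ``data[x, y, z, t]`` plus geometry."""

    data: np.ndarray
    geom: AcquisitionGeometry
    subject_id: str = ""
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 4:
            raise ValueError("session data must be 4-D (x, y, z, t)")
        if self.data.shape[3] != self.geom.n_vols:
            raise ValueError(
                f"data has {self.data.shape[3]} frames, geometry says {self.geom.n_vols}"
            )

    @property
    def n_vols(self) -> int:
        return self.data.shape[3]

    @property
    def grid_shape(self) -> tuple:
        return self.data.shape[:3]

    def mean_volume(self) -> np.ndarray:
        return self.data.mean(axis=3)

    def with_data(self, data: np.ndarray, **prov) -> "Session4D":
        new = Session4D(data, self.geom, self.subject_id, dict(self.provenance))
        new.provenance.update(prov)
        return new

    def copy(self) -> "Session4D":
        return Session4D(self.data.copy(), self.geom, self.subject_id, dict(self.provenance))

    def to_nifti(self) -> nib.Nifti1Image:
        img = nib.Nifti1Image(np.asarray(self.data, dtype=np.float32), self.geom.affine())
        img.header.set_zooms((*self.geom.spacing_mm, self.geom.tr_s))
        return img

    def save(self, path) -> None:
        nib.save(self.to_nifti(), str(path))


def load_session(path, tr_s: float | None = None) -> Session4D:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=np.float32)
    zooms = img.header.get_zooms()
    tr = tr_s if tr_s is not None else (zooms[3] if len(zooms) > 3 and zooms[3] > 0 else 3.0)
    geom = AcquisitionGeometry(
        n_vols=data.shape[3],
        tr_s=float(tr),
        grid_shape=data.shape[:3],
        voxel_mm=(float(zooms[0]), float(zooms[1]), float(zooms[2])),
        slice_gap_mm=0.0,
    )
    return Session4D(data, geom)


# ---------------------------------------------------------------------------
# rigid-body transforms
# ---------------------------------------------------------------------------

def rotation_matrix(rx_deg: float, ry_deg: float, rz_deg: float) -> np.ndarray:
    """World-space rotation, applied as Rz @ Ry @ Rx."""
    rx, ry, rz = np.deg2rad([rx_deg, ry_deg, rz_deg])
    cx, sx, cy, sy, cz, sz = np.cos(rx), np.sin(rx), np.cos(ry), np.sin(ry), np.cos(rz), np.sin(rz)
    Rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    Ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    Rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    return Rz @ Ry @ Rx


def apply_rigid(
    volume: np.ndarray,
    params,
    spacing_mm,
    inverse: bool = False,
    order: int = 1,
    mode: str = "constant",
    cval: float = 0.0,
) -> np.ndarray:
    """Resample a 3-D volume under a rigid-body transform.

    ``params`` is ``(tx, ty, tz, rx, ry, rz)`` in mm and degrees: the motion
    of the imaged object about the grid centre.  ``inverse=True`` applies the
    inverse transform (i.e. undoes that motion).  Trilinear by default, which
    is exact for integer-voxel translations.
    """
    params = np.asarray(params, dtype=float)
    if not np.all(np.isfinite(params)):
        raise ValueError("rigid parameters must be finite")
    if np.all(params == 0):
        return volume.copy()
    t = params[:3]
    R = rotation_matrix(*params[3:6])
    if inverse:
        R, t = R.T, -R.T @ t
    # output voxel -> input voxel: v_in = S^-1 R^T S (v_out - c) - S^-1 R^T t + c
    S = np.diag(np.asarray(spacing_mm, dtype=float))
    Sinv = np.diag(1.0 / np.asarray(spacing_mm, dtype=float))
    c = (np.array(volume.shape) - 1) / 2.0
    M = Sinv @ R.T @ S
    offset = c - M @ c - Sinv @ R.T @ t
    return ndimage.affine_transform(
        volume.astype(float), M, offset=offset, order=order, mode=mode, cval=cval
    )
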