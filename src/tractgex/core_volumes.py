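"""Volume and affine-transform data model with NIfTI-1 I/O.

Every image handled by this package -- fractional-anisotropy (FA) maps,
anatomical templates, reconstructed Nissl stacks, gene-expression "energy"
maps, masks and p-maps -- is carried by a single :class:`Volume` type: a 3D
scalar grid with voxel spacing in mm and a voxel-to-world affine (RAS,
0-based voxel indices).  Spatial mappings between volumes are 12-parameter
affine transforms (:class:`AffineTransform`) acting on world coordinates.

Energy maps use a sentinel value (conventionally -1) to mark voxels with no
expression annotation; all statistics downstream exclude those voxels.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import nibabel as nib
import numpy as np

__all__ = [
    "Volume",
    "AffineTransform",
    "read_volume",
    "write_volume",
    "set_header_spacing",
    "rgb_to_gray",
    "stack_slices_to_volume",
]

#: ITU-R 601 luminance weights used for gray-scaling RGB stacks.
GRAY_WEIGHTS = (0.299, 0.587, 0.114)


def _spacing_from_affine(affine: np.ndarray) -> np.ndarray:
    return np.linalg.norm(np.asarray(affine, dtype=float)[:3, :3], axis=0)


@dataclass
class Volume:
    """A 3D scalar grid with geometry.

    Parameters
    ----------
    data
        3D array of intensities (FA is dimensionless in [0, 1]; energy maps
        are in arbitrary expression-energy units).
    affine_vox2world
        4x4 matrix mapping 0-based voxel index (i, j, k, 1) to world mm (RAS).
    missing_value
        Optional sentinel marking "no data" voxels (energy-map convention: -1).
        Statistics and interpolation exclude voxels equal to it.
    """

    data: np.ndarray
    affine_vox2world: np.ndarray = field(default_factory=lambda: np.eye(4))
    missing_value: Optional[float] = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3 or min(self.data.shape) < 1:
            raise ValueError(
                f"Volume data must be 3D with each axis >= 1, got shape {self.data.shape}"
            )
        self.affine_vox2world = np.asarray(self.affine_vox2world, dtype=float)
        if self.affine_vox2world.shape != (4, 4):
            raise ValueError("affine_vox2world must be 4x4")
        if abs(np.linalg.det(self.affine_vox2world[:3, :3])) < 1e-15:
            raise ValueError("affine_vox2world must be invertible")
        if np.any(self.spacing <= 0):
            raise ValueError("voxel spacing must be strictly positive")

    @property
    def spacing(self) -> np.ndarray:
        """Per-axis voxel size in mm (norms of the affine columns)."""
        return _spacing_from_affine(self.affine_vox2world)

    @property
    def shape(self) -> tuple:
        return self.data.shape

    def copy(self, data: Optional[np.ndarray] = None) -> "Volume":
        return Volume(
            data=self.data.copy() if data is None else np.asarray(data),
            affine_vox2world=self.affine_vox2world.copy(),
            missing_value=self.missing_value,
        )

    def valid_mask(self) -> np.ndarray:
        """Boolean mask of voxels carrying data (False where == missing_value)."""
        if self.missing_value is None:
            return np.ones(self.shape, dtype=bool)
        return self.data != self.missing_value

    def vox_to_world(self, vox: np.ndarray) -> np.ndarray:
        """Map (N, 3) voxel indices (fractional allowed) to (N, 3) world mm."""
        vox = np.atleast_2d(np.asarray(vox, dtype=float))
        h = np.hstack([vox, np.ones((len(vox), 1))])
        return (self.affine_vox2world @ h.T).T[:, :3]

    def world_to_vox(self, world: np.ndarray) -> np.ndarray:
        world = np.atleast_2d(np.asarray(world, dtype=float))
        inv = np.linalg.inv(self.affine_vox2world)
        h = np.hstack([world, np.ones((len(world), 1))])
        return (inv @ h.T).T[:, :3]

    def world_center(self) -> np.ndarray:
        """World coordinate of the grid centre (mm)."""
        c = (np.asarray(self.shape, dtype=float) - 1.0) / 2.0
        return self.vox_to_world(c)[0]

    def grid_like(self) -> "Volume":
        """An empty (zeros) volume on the same grid -- handy as a target grid."""
        return Volume(
            np.zeros(self.shape, dtype=float),
            self.affine_vox2world.copy(),
            self.missing_value,
        )


def _rotation_matrix(rx_deg: float, ry_deg: float, rz_deg: float) -> np.ndarray:
    rx, ry, rz = (math.radians(a) for a in (rx_deg, ry_deg, rz_deg))
    cx, sx = math.cos(rx), math.sin(rx)
    cy, sy = math.cos(ry), math.sin(ry)
    cz, sz = math.cos(rz), math.sin(rz)
    Rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    Ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    Rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    return Rz @ Ry @ Rx


@dataclass
class AffineTransform:
    """A 12-parameter spatial mapping between world frames (mm -> mm).

    ``params`` are ordered ``(tx, ty, tz, rx, ry, rz, sx, sy, sz, hxy, hxz,
    hyz)``: translations in mm, rotations in degrees, per-axis scales and the
    three upper-triangular shears.  The homogeneous matrix is built as
    ``T . C . Rz Ry Rx . Shear . Scale . C^-1`` about an optional world centre
    ``C`` -- identity parameters always give the identity matrix.
    """

    matrix: np.ndarray
    params: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape != (4, 4):
            raise ValueError("transform matrix must be 4x4")
        det = np.linalg.det(self.matrix[:3, :3])
        if det <= 1e-12:
            raise ValueError(f"transform must be invertible with positive determinant, det={det:g}")
        if self.params is not None:
            self.params = np.asarray(self.params, dtype=float)

    # -- constructors ----------------------------------------------------
    @classmethod
    def identity(cls) -> "AffineTransform":
        return cls(np.eye(4), cls.identity_params())

    @staticmethod
    def identity_params() -> np.ndarray:
        return np.array([0, 0, 0, 0, 0, 0, 1, 1, 1, 0, 0, 0], dtype=float)

    @classmethod
    def from_params(
        cls, params: Sequence[float], center: Optional[Sequence[float]] = None
    ) -> "AffineTransform":
        p = np.asarray(params, dtype=float)
        if p.shape != (12,):
            raise ValueError("expected 12 parameters")
        R = _rotation_matrix(p[3], p[4], p[5])
        S = np.diag(p[6:9])
        H = np.array([[1, p[9], p[10]], [0, 1, p[11]], [0, 0, 1]], dtype=float)
        A = R @ H @ S
        m = np.eye(4)
        m[:3, :3] = A
        c = np.zeros(3) if center is None else np.asarray(center, dtype=float)
        m[:3, 3] = p[:3] + c - A @ c
        return cls(m, p)

    @classmethod
    def from_matrix(cls, matrix: np.ndarray) -> "AffineTransform":
        return cls(np.asarray(matrix, dtype=float))

    # -- algebra ---------------------------------------------------------
    def inverse(self) -> "AffineTransform":
        return AffineTransform(np.linalg.inv(self.matrix))

    def then(self, other: "AffineTransform") -> "AffineTransform":
        """The transform applying ``self`` first, then ``other``."""
        return AffineTransform(other.matrix @ self.matrix)

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Apply to (N, 3) world points."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        h = np.hstack([pts, np.ones((len(pts), 1))])
        return (self.matrix @ h.T).T[:, :3]

    # -- serialization ---------------------------------------------------
    def to_dict(self, source_space: str = "", target_space: str = "") -> dict:
        d = {
            "source_space": source_space,
            "target_space": target_space,
            "matrix": [float(v) for v in self.matrix.ravel()],
        }
        if self.params is not None:
            d["params"] = [float(v) for v in self.params]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "AffineTransform":
        m = np.asarray(d["matrix"], dtype=float).reshape(4, 4)
        p = np.asarray(d["params"], dtype=float) if "params" in d else None
        return cls(m, p)


# ---------------------------------------------------------------------------
# NIfTI-1 I/O
# ---------------------------------------------------------------------------

def read_volume(path, missing_value: Optional[float] = None) -> Volume:
    """Read a NIfTI-1 file into a :class:`Volume`.

    The qform is authoritative when set; otherwise nibabel's best affine is
    used.  4D images are accepted only when all non-spatial axes are
    singletons.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such volume: {path}")
    try:
        img = nib.load(str(path))
        data = np.asarray(img.dataobj)
    except Exception as exc:  # nibabel raises a zoo of types on bad payloads
        raise ValueError(f"invalid NIfTI file: {path} ({exc})") from exc
    if data.ndim > 3:
        non_singleton = [s for s in data.shape[3:] if s != 1]
        if non_singleton:
            raise ValueError(
                f"expected 3D (or singleton-trailing) image, got shape {data.shape}"
            )
        data = data.reshape(data.shape[:3])
    if data.ndim < 3:
        raise ValueError(f"expected 3D image, got shape {data.shape}")
    qform, qcode = img.header.get_qform(coded=True)
    affine = qform if (qcode is not None and int(qcode) > 0) else img.affine
    return Volume(np.asarray(data, dtype=np.float32), affine, missing_value)


def write_volume(vol: Volume, path) -> None:
    """Write a :class:`Volume` as NIfTI-1 (float32 data).

    Round-trips through :func:`read_volume` preserve float32 data bit-exactly
    (including any ``missing_value`` sentinel voxels).
    """
    path = Path(path)
    if not path.parent.exists():
        raise FileNotFoundError(f"parent directory does not exist: {path.parent}")
    img = nib.Nifti1Image(np.asarray(vol.data, dtype=np.float32), vol.affine_vox2world)
    img.header.set_qform(vol.affine_vox2world, code=1)
    img.header.set_sform(vol.affine_vox2world, code=1)
    nib.save(img, str(path))


def set_header_spacing(vol: Volume, new_spacing) -> Volume:
    """Re-declare the voxel size in the header, leaving the data untouched.

    This reproduces the small-animal trick of relabelling ultra-high-resolution
    voxels (e.g. 39 um or 125 um) as 1 mm isotropic so that human-calibrated
    tooling accepts the files: only the geometry metadata changes, the raw
    data matrix is byte-identical.
    """
    new_spacing = np.asarray(new_spacing, dtype=float)
    if new_spacing.shape == ():
        new_spacing = np.repeat(new_spacing, 3)
    if new_spacing.shape != (3,) or np.any(new_spacing <= 0):
        raise ValueError(f"new_spacing must be 3 strictly positive values, got {new_spacing}")
    old = vol.spacing
    affine = vol.affine_vox2world.copy()
    affine[:3, :3] = affine[:3, :3] * (new_spacing / old)[None, :]
    return Volume(vol.data, affine, vol.missing_value)


def rgb_to_gray(stack: np.ndarray, affine_vox2world: Optional[np.ndarray] = None) -> Volume:
    """Collapse a 3-channel image stack to a single gray channel.

    Uses the fixed luminance weighting 0.299 R + 0.587 G + 0.114 B; output
    values stay within the [min, max] range of the inputs, and replicated-gray
    input is returned unchanged.
    """
    stack = np.asarray(stack, dtype=float)
    if stack.ndim != 4 or stack.shape[-1] != 3:
        raise ValueError(
            f"expected a 3-channel stack of shape (X, Y, Z, 3), got {stack.shape}"
        )
    w = np.asarray(GRAY_WEIGHTS)
    gray = stack @ w
    affine = np.eye(4) if affine_vox2world is None else affine_vox2world
    return Volume(gray, affine)


def stack_slices_to_volume(
    slices: Sequence[np.ndarray], slice_spacing: float, in_plane_spacing
) -> Volume:
    """Reconstruct a 3D volume from an ordered list of 2D sections.

    Axis 0 of the result is the slice axis (sagittal by the atlas convention
    used here); voxel ``(k, i, j)`` equals ``slices[k][i, j]``.
    """
    if len(slices) == 0:
        raise ValueError("need at least one slice")
    arrs = [np.asarray(s, dtype=float) for s in slices]
    shape0 = arrs[0].shape
    if any(a.ndim != 2 or a.shape != shape0 for a in arrs):
        raise ValueError("all slices must be 2D arrays of identical shape")
    ip = np.asarray(in_plane_spacing, dtype=float)
    if ip.shape == ():
        ip = np.repeat(ip, 2)
    spacing = np.array([float(slice_spacing), ip[0], ip[1]])
    if np.any(spacing <= 0):
        raise ValueError("spacings must be strictly positive")
    affine = np.diag([spacing[0], spacing[1], spacing[2], 1.0])
    return Volume(np.stack(arrs, axis=0), affine)


def volume_from_spacing(
    data: np.ndarray,
    spacing,
    origin=(0.0, 0.0, 0.0),
    missing_value: Optional[float] = None,
) -> Volume:
    """Build a Volume on an axis-aligned grid from spacing and world origin."""
    spacing = np.asarray(spacing, dtype=float)
    if spacing.shape == ():
        spacing = np.repeat(spacing, 3)
    affine = np.diag([spacing[0], spacing[1], spacing[2], 1.0])
    affine[:3, 3] = np.asarray(origin, dtype=float)
    return Volume(data, affine, missing_value)
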