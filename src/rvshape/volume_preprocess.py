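"""Segmentation-volume preprocessing.

Turns heterogeneous binary segmentation volumes into identically sampled,
rigidly aligned signed distance transforms, the common substrate for
particle-based correspondence optimization.

Conventions (fixed here, asserted in tests):

* Array axes are (x, y, z); world coordinate of voxel ``(i, j, k)`` is
  ``origin + (i, j, k) * spacing``.
* Signed distance is **negative inside** the shape and is measured to the
  voxel *face* interface: a voxel center adjacent to the boundary has
  ``|d| = spacing / 2``.
* Alignment is translation-only by default (common grid, foreground
  centroids moved to the grid center); principal-axis rotation is opt-in.
  No size normalization is ever applied — ventricular dilation is signal,
  not nuisance.
"""

from __future__ import annotations

import dataclasses
import os
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

import nibabel as nib

#: Default isotropic resampling pitch in mm, between typical short-axis
#: in-plane resolution (~1.25-1.56 mm) and slice thickness (6 mm).
DEFAULT_SPACING = 1.5

#: Margin (voxels) kept between foreground and the grid boundary.
ALIGN_MARGIN = 4


@dataclass
class SegmentationMask:
    """Binary voxel volume for one subject's RV blood pool.

    Attributes
    ----------
    voxels : (nx, ny, nz) bool array
    spacing : (3,) float array, mm per axis
    origin : (3,) float array, world position (mm) of voxel (0, 0, 0)
    subject_id : str
    """

    voxels: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels).astype(bool)
        self.spacing = np.broadcast_to(
            np.asarray(self.spacing, dtype=float), (3,)
        ).copy()
        self.origin = np.asarray(self.origin, dtype=float).reshape(3).copy()
        if self.voxels.ndim != 3:
            raise ValueError("voxels must be a 3-D array")
        if np.any(self.spacing <= 0):
            raise ValueError("spacing must be positive")

    @property
    def is_isotropic(self) -> bool:
        return bool(np.allclose(self.spacing, self.spacing[0]))

    def foreground_count(self) -> int:
        return int(self.voxels.sum())

    def volume(self) -> float:
        """Foreground volume in mm^3 (count x voxel volume)."""
        return self.foreground_count() * float(np.prod(self.spacing))

    def centroid_world(self) -> np.ndarray:
        """Foreground centroid in world coordinates (mm)."""
        if self.foreground_count() == 0:
            raise ValueError("mask has no foreground voxels")
        idx = np.asarray(ndimage.center_of_mass(self.voxels), dtype=float)
        return self.origin + idx * self.spacing

    def copy(self) -> "SegmentationMask":
        return SegmentationMask(
            self.voxels.copy(), self.spacing.copy(), self.origin.copy(),
            self.subject_id,
        )


@dataclass
class DistanceTransform:
    """Signed Euclidean distance field (mm), inside-negative."""

    values: np.ndarray
    spacing: float
    origin: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float32)
        self.spacing = float(self.spacing)
        self.origin = np.asarray(self.origin, dtype=float).reshape(3).copy()

    @property
    def shape(self):
        return self.values.shape

    def world_to_index(self, points: np.ndarray) -> np.ndarray:
        return (np.atleast_2d(points) - self.origin) / self.spacing

    def index_to_world(self, idx: np.ndarray) -> np.ndarray:
        return self.origin + np.atleast_2d(idx) * self.spacing


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def resample_isotropic(
    mask: SegmentationMask, target_spacing: float = DEFAULT_SPACING
) -> SegmentationMask:
    """Resample a binary mask onto an isotropic grid.

    Linear interpolation of the indicator followed by a 0.5 threshold
    (a majority rule), which conserves foreground volume to well within
    the 5 % contract for smooth shapes.
    """
    if target_spacing <= 0:
        raise ValueError("target_spacing must be positive")
    if mask.foreground_count() == 0:
        raise ValueError("cannot resample an empty mask")
    if np.allclose(mask.spacing, target_spacing):
        return mask.copy()
    zoom = mask.spacing / float(target_spacing)
    resampled = ndimage.zoom(
        mask.voxels.astype(np.float32), zoom, order=1, mode="constant",
        cval=0.0, grid_mode=True,
    )
    out = resampled > 0.5
    if not out.any():
        raise ValueError("resampling produced an empty mask")
    return SegmentationMask(
        out, np.full(3, float(target_spacing)), mask.origin, mask.subject_id
    )


def _bounding_extent(mask: SegmentationMask) -> np.ndarray:
    idx = np.argwhere(mask.voxels)
    return idx.max(axis=0) - idx.min(axis=0) + 1


def _principal_rotation(mask: SegmentationMask) -> np.ndarray:
    """Rotation matrix sending the mask's principal axes to the grid axes.

    Axis signs are disambiguated by the third central moment along each
    principal direction so the decomposition is deterministic.
    """
    idx = np.argwhere(mask.voxels).astype(float)
    centered = (idx - idx.mean(axis=0)) * mask.spacing
    cov = centered.T @ centered / len(centered)
    eigvals, eigvecs = np.linalg.eigh(cov)
    order = np.argsort(eigvals)[::-1]
    axes = eigvecs[:, order]
    proj = centered @ axes
    skew = (proj ** 3).mean(axis=0)
    signs = np.where(skew >= 0, 1.0, -1.0)
    axes = axes * signs
    if np.linalg.det(axes) < 0:
        axes[:, 2] = -axes[:, 2]
    return axes


def _centroid_aligned(voxels, dims, center, offset0) -> np.ndarray:
    """Shift a binary mask onto the common grid so its centroid lands on
    the grid center to sub-voxel accuracy.

    The centroid of the thresholded, interpolated mask is a staircase
    function of the fractional offset, so a fixed-point update cannot
    converge; instead each axis's fractional offset is chosen by a direct
    search over candidates, minimizing the realized centroid error.
    """
    src = voxels.astype(np.float32)
    out_shape = tuple(int(d) for d in dims)
    dims = np.asarray(dims)

    def realize(off):
        sh = ndimage.affine_transform(
            src, np.eye(3), offset=off, output_shape=out_shape,
            order=1, mode="constant", cval=0.0,
        ) > 0.5
        if not sh.any():
            return sh, None
        return sh, np.asarray(ndimage.center_of_mass(sh)) - center

    def realize_super(off):
        # sample the shifted indicator on a 2x supersampled grid and
        # majority-pool back; the finer sampling decorrelates threshold
        # flips, so the centroid responds almost continuously to the shift
        n = dims * 2
        a = np.diag([0.5, 0.5, 0.5])
        o = np.asarray(off) + center - a @ ((n - 1) / 2.0)
        fine = ndimage.affine_transform(
            src, a, offset=o, output_shape=tuple(int(d) for d in n),
            order=1, mode="constant", cval=0.0,
        )
        coarse = fine.reshape(dims[0], 2, dims[1], 2, dims[2], 2) \
                     .mean(axis=(1, 3, 5))
        sh = coarse > 0.5
        if not sh.any():
            return sh, None
        return sh, np.asarray(ndimage.center_of_mass(sh)) - center

    def search(fn, start_off, rounds):
        _, e = fn(start_off)
        if e is None:
            return start_off, np.inf
        best_off, best_norm = np.array(start_off), float(np.linalg.norm(e))
        for deltas in rounds:
            for axis in range(3):
                for delta in deltas:
                    cand = best_off.copy()
                    cand[axis] += delta
                    _, e = fn(cand)
                    if e is not None and \
                            np.linalg.norm(e) < best_norm - 1e-6:
                        best_off = cand
                        best_norm = float(np.linalg.norm(e))
                if best_norm < 0.08:
                    return best_off, best_norm
        return best_off, best_norm

    offset = np.asarray(offset0, dtype=float)
    off, norm = search(
        realize, offset,
        (np.linspace(-0.6, 0.6, 13), np.linspace(-0.1, 0.1, 9)),
    )
    if norm <= 0.18 or not np.isfinite(norm):
        return realize(off)[0]
    off2, norm2 = search(
        realize_super, off,
        (np.linspace(-0.4, 0.4, 9), np.linspace(-0.08, 0.08, 9)),
    )
    if norm2 > 0.2:
        # coordinate descent stalls on the piecewise-constant landscape;
        # probe around the start with a fixed-seed scatter, then refine
        rng = np.random.default_rng(0)
        for _ in range(40):
            cand = offset + rng.uniform(-0.45, 0.45, 3)
            _, e = realize_super(cand)
            if e is not None and np.linalg.norm(e) < norm2:
                off2, norm2 = cand, float(np.linalg.norm(e))
        off2, norm2 = search(realize_super, off2,
                             (np.linspace(-0.08, 0.08, 9),))
    if norm2 < norm:
        return realize_super(off2)[0]
    return realize(off)[0]


def align_rigid(
    masks: list[SegmentationMask], rotate: bool = False
) -> list[SegmentationMask]:
    """Place all masks on one common grid with coincident centroids.

    All outputs share identical dimensions; every foreground centroid sits
    at the grid center to sub-voxel accuracy. With ``rotate=True`` each
    mask is first rotated so its principal axes match the grid axes
    (deterministic sign convention via third moments).
    """
    if len(masks) == 0:
        raise ValueError("align_rigid requires at least one mask")
    spacings = np.array([m.spacing for m in masks])
    if not np.allclose(spacings, spacings[0, 0]):
        raise ValueError("all masks must share one isotropic spacing")
    s = float(spacings[0, 0])

    work = []
    for m in masks:
        if m.foreground_count() == 0:
            raise ValueError(f"mask {m.subject_id!r} is empty")
        if rotate:
            work.append(_rotate_to_principal(m))
        else:
            work.append(m)

    extents = np.array([_bounding_extent(m) for m in work])
    dims = extents.max(axis=0) + 2 * ALIGN_MARGIN
    center = (dims - 1) / 2.0
    common_origin = -center * s

    out = []
    for m in work:
        src_centroid = np.asarray(ndimage.center_of_mass(m.voxels))
        # output index u samples input at u + (src_centroid - center);
        # thresholding perturbs the centroid slightly, so refine the
        # offset by fixed-point iteration until sub-0.1-voxel accuracy
        offset = src_centroid - center
        if (tuple(dims) == m.voxels.shape
                and np.linalg.norm(offset) < 0.22):
            # already centred to tolerance: keep voxels untouched so the
            # pipeline is idempotent
            shifted = m.voxels.copy()
        else:
            shifted = _centroid_aligned(m.voxels, dims, center, offset)
        if shifted is None or not shifted.any():
            raise ValueError(f"alignment emptied mask {m.subject_id!r}")
        out.append(
            SegmentationMask(shifted, np.full(3, s), common_origin,
                             m.subject_id)
        )
    return out


def _rotate_to_principal(mask: SegmentationMask) -> SegmentationMask:
    axes = _principal_rotation(mask)
    centroid = np.asarray(ndimage.center_of_mass(mask.voxels))
    # resample: output index u -> input index axes @ (u - c) + c
    rotated = ndimage.affine_transform(
        mask.voxels.astype(np.float32),
        axes,
        offset=centroid - axes @ centroid,
        order=1,
        mode="constant",
        cval=0.0,
    ) > 0.5
    return SegmentationMask(rotated, mask.spacing, mask.origin,
                            mask.subject_id)


def signed_distance_transform(mask: SegmentationMask) -> DistanceTransform:
    """Exact Euclidean signed distance (mm), inside-negative.

    Distances are to the voxel-face interface: the Euclidean distance
    between voxel centers across the boundary minus half a voxel.
    """
    if not mask.is_isotropic:
        raise ValueError("signed_distance_transform requires isotropic mask")
    fg = mask.voxels
    if fg.all():
        raise ValueError("mask is all foreground; no interface exists")
    if not fg.any():
        raise ValueError("mask is all background; no interface exists")
    s = float(mask.spacing[0])
    d_out = ndimage.distance_transform_edt(~fg, sampling=s)
    d_in = ndimage.distance_transform_edt(fg, sampling=s)
    signed = np.where(fg, -(d_in - s / 2.0), d_out - s / 2.0)
    return DistanceTransform(signed.astype(np.float32), s, mask.origin)


def preprocess_cohort(
    masks: list[SegmentationMask],
    target_spacing: float = DEFAULT_SPACING,
    rotate: bool = False,
) -> tuple[list[SegmentationMask], list[DistanceTransform]]:
    """Resample -> align -> signed distance transform, for a whole cohort."""
    iso = [resample_isotropic(m, target_spacing) for m in masks]
    aligned = align_rigid(iso, rotate=rotate)
    dts = [signed_distance_transform(m) for m in aligned]
    return aligned, dts


# ---------------------------------------------------------------------------
# File I/O (NIfTI via nibabel; MetaImage by hand)
# ---------------------------------------------------------------------------

def write_mask_nifti(mask: SegmentationMask, path: str) -> None:
    affine = np.diag(np.append(mask.spacing, 1.0))
    affine[:3, 3] = mask.origin
    img = nib.Nifti1Image(mask.voxels.astype(np.uint8), affine)
    nib.save(img, path)


def read_mask_nifti(path: str, subject_id: str = "") -> SegmentationMask:
    img = nib.load(path)
    affine = img.affine
    spacing = np.abs(np.diag(affine)[:3])
    origin = affine[:3, 3]
    data = np.asanyarray(img.dataobj) > 0.5
    return SegmentationMask(data, spacing, origin,
                            subject_id or os.path.basename(path))


def write_dt_nifti(dt: DistanceTransform, path: str) -> None:
    affine = np.diag([dt.spacing] * 3 + [1.0])
    affine[:3, 3] = dt.origin
    nib.save(nib.Nifti1Image(dt.values.astype(np.float32), affine), path)


def read_dt_nifti(path: str) -> DistanceTransform:
    img = nib.load(path)
    spacing = float(np.abs(img.affine[0, 0]))
    return DistanceTransform(
        np.asanyarray(img.dataobj).astype(np.float32), spacing,
        img.affine[:3, 3],
    )


def write_mask_metaimage(mask: SegmentationMask, path: str) -> None:
    """Write an uncompressed MetaImage (.mhd header + .raw payload)."""
    if not path.endswith(".mhd"):
        raise ValueError("MetaImage path must end in .mhd")
    raw_path = path[:-4] + ".raw"
    # MetaImage is Fortran-order along x-fastest; our axes are already (x,y,z)
    data = np.ascontiguousarray(mask.voxels.astype(np.uint8).transpose(2, 1, 0))
    dims = mask.voxels.shape
    header = "\n".join([
        "ObjectType = Image",
        "NDims = 3",
        "BinaryData = True",
        "BinaryDataByteOrderMSB = False",
        f"DimSize = {dims[0]} {dims[1]} {dims[2]}",
        f"ElementSpacing = {mask.spacing[0]} {mask.spacing[1]} {mask.spacing[2]}",
        f"Offset = {mask.origin[0]} {mask.origin[1]} {mask.origin[2]}",
        "ElementType = MET_UCHAR",
        f"ElementDataFile = {os.path.basename(raw_path)}",
        "",
    ])
    with open(path, "w") as fh:
        fh.write(header)
    data.tofile(raw_path)


def read_mask_metaimage(path: str, subject_id: str = "") -> SegmentationMask:
    fields: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            if "=" in line:
                k, v = line.split("=", 1)
                fields[k.strip()] = v.strip()
    dims = [int(x) for x in fields["DimSize"].split()]
    spacing = [float(x) for x in fields["ElementSpacing"].split()]
    origin = [float(x) for x in fields.get("Offset", "0 0 0").split()]
    raw_path = os.path.join(os.path.dirname(path), fields["ElementDataFile"])
    data = np.fromfile(raw_path, dtype=np.uint8)
    data = data.reshape(dims[2], dims[1], dims[0]).transpose(2, 1, 0)
    return SegmentationMask(data > 0, np.asarray(spacing), np.asarray(origin),
                            subject_id or os.path.basename(path))


def dataclass_replace(obj, **kw):
    return dataclasses.replace(obj, **kw)
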