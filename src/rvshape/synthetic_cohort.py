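"""Synthetic right-ventricle-like shape cohorts with known ground truth.

Real RV segmentations are not distributable, so every pipeline stage is
exercised on a synthetic cohort that mimics the study population's
statistical structure: a star-shaped, axially asymmetric template (a
crescent-sectioned half-ellipsoid standing in for the RV blood pool),
group-level deformation fields with the directions reported for disease
(free-wall bulging, apex blunting and base widening in tricuspid
regurgitation; inward mid-free-wall displacement in comorbid controls; a
narrowed "streamlined" mid-cavity in pulmonary-hypertension controls), and
smooth subject-level radial noise.

Because every surface is expressed as a radius field r(theta, phi) over one
shared spherical parameter grid, the generator knows the exact
correspondence between subjects: the point at parameter (theta_j, phi_k) is
anatomically "the same" location on every subject. That ground truth is
what makes the correspondence optimizer and the downstream statistics
testable without patient data.

Parameter-space landmarks (template coordinates; theta is colatitude from
the base pole at theta=0 to the apex pole at theta=pi, phi=0 faces the free
wall, phi=pi the septum):

* free-wall patch: pi/4 < theta < 3*pi/4 and |phi| < pi/2
* base cap:        theta < pi/4
* apex cap:        theta > 3*pi/4
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.special import sph_harm_y

from .volume_preprocess import SegmentationMask

GROUPS = ("healthy", "control", "tr")
SUBGROUPS = ("phtn", "chf", "other", "none")

# Template half-ellipsoid radii (mm): x (free wall <-> septum), y, z (long axis)
TEMPLATE_RADII = (22.0, 16.0, 35.0)
# Depth of the septal crescent indentation (relative)
CRESCENT_DEPTH = 0.25

# Deformation bump centers/widths in (theta, phi), radians
BULGE_CENTER, BULGE_WIDTH = (math.pi / 2, 0.0), 0.45
PINCH_CENTER, PINCH_WIDTH = (math.pi / 2, 0.0), 0.35
APEX_WIDTH = 0.40
BASE_CENTER, BASE_WIDTH = math.pi / 5, 0.35
STREAMLINE_WIDTH = 0.40

NOISE_DEGREE = 4  # max spherical-harmonic degree of the subject noise field

MIN_RESOLUTION = 16


def _wrap_angle(phi):
    """Wrap to (-pi, pi]."""
    return (np.asarray(phi) + math.pi) % (2 * math.pi) - math.pi


def free_wall_patch(theta, phi):
    """Boolean mask of the designated free-wall patch."""
    theta = np.asarray(theta)
    return (
        (theta > math.pi / 4)
        & (theta < 3 * math.pi / 4)
        & (np.abs(_wrap_angle(phi)) < math.pi / 2)
    )


def apex_cap(theta, phi=None):
    return np.asarray(theta) > 3 * math.pi / 4


def base_cap(theta, phi=None):
    return np.asarray(theta) < math.pi / 4


@dataclass
class DeformationParams:
    """Group-level deformation amplitudes (mm).

    Directions come from the disease phenotype; magnitudes are free
    parameters of the generator (the source study reports directions and
    significance maps, not millimetre effect sizes).
    """

    bulge_amp: float = 5.0
    apex_blunt_amp: float = 3.0
    base_width_amp: float = 3.0
    midwall_pinch_amp: float = 2.0
    streamline_amp: float = 2.5


@dataclass
class CohortSpec:
    """Specification of one synthetic cohort.

    Defaults reproduce the study composition: 6 healthy volunteers, 27
    comorbidity-matched controls and 21 patients with TR (54 subjects).
    ``landmark_jitter_sd`` adds isotropic 3-D jitter to the ground-truth
    correspondence points only (emulating landmark placement error); it is
    off by default so correspondences lie exactly on the surface.
    """

    group_sizes: dict = field(
        default_factory=lambda: {"healthy": 6, "control": 27, "tr": 21}
    )
    subgroup_fractions: dict = field(
        default_factory=lambda: {
            "control": {"phtn": 0.4, "chf": 0.4, "other": 0.2},
            "tr": {"phtn": 0.4, "chf": 0.4, "other": 0.2},
        }
    )
    deformation_params: DeformationParams = field(
        default_factory=DeformationParams
    )
    noise_sd: float = 1.0
    landmark_jitter_sd: float = 0.0
    voxel_spacing: float = 1.5
    grid_dims: int = 64
    gt_resolution: int = 24
    seed: int = 0

    def validate(self) -> None:
        for g, n in self.group_sizes.items():
            if g not in GROUPS:
                raise ValueError(f"unknown group {g!r}")
            if n < 0:
                raise ValueError("group counts must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.landmark_jitter_sd < 0:
            raise ValueError("landmark_jitter_sd must be >= 0")
        if self.voxel_spacing <= 0:
            raise ValueError("voxel_spacing must be positive")
        for g, fr in self.subgroup_fractions.items():
            total = sum(fr.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(
                    f"subgroup fractions for {g!r} sum to {total}, not 1"
                )


class _HarmonicField:
    """Smooth random scalar field on the sphere.

    Low-order real spherical harmonics with iid normal coefficients,
    scaled (via the addition theorem) so the pointwise standard deviation
    equals ``sd`` exactly.
    """

    def __init__(self, sd: float, rng: np.random.Generator,
                 degree: int = NOISE_DEGREE):
        self.degree = degree
        n_coef = (degree + 1) ** 2
        unit_var = sum(2 * l + 1 for l in range(degree + 1)) / (4 * math.pi)
        scale = sd / math.sqrt(unit_var) if sd > 0 else 0.0
        self.coeffs = rng.standard_normal(n_coef) * scale

    def __call__(self, theta, phi):
        theta = np.asarray(theta, dtype=float)
        phi = np.asarray(phi, dtype=float)
        out = np.zeros(np.broadcast(theta, phi).shape)
        if not np.any(self.coeffs):
            return out
        i = 0
        for l in range(self.degree + 1):
            for m in range(-l, l + 1):
                y = sph_harm_y(l, abs(m), theta, phi)
                if m == 0:
                    basis = y.real
                elif m > 0:
                    basis = math.sqrt(2.0) * y.real
                else:
                    basis = math.sqrt(2.0) * y.imag
                out = out + self.coeffs[i] * basis
                i += 1
        return out


def _gauss_bump(theta, phi, center, width):
    dt = np.asarray(theta) - center[0]
    dp = _wrap_angle(np.asarray(phi) - center[1])
    return np.exp(-(dt ** 2 + dp ** 2) / (2 * width ** 2))


class GroundTruthShape:
    """A star-shaped surface r(theta, phi) with exact correspondence.

    The radius field is the template plus group deformation bumps plus an
    optional smooth noise field; it is evaluable at arbitrary angles, so
    ground-truth correspondence points are analytic, not interpolated.
    """

    def __init__(self, resolution: int = 24, group: str = "healthy",
                 subgroup: str = "none"):
        if resolution < MIN_RESOLUTION:
            raise ValueError(
                f"resolution must be >= {MIN_RESOLUTION} samples per axis, "
                f"got {resolution}"
            )
        self.resolution = resolution
        self.group = group
        self.subgroup = subgroup
        self._bumps: list[tuple[float, object]] = []  # (amplitude, field fn)
        self._noise: _HarmonicField | None = None
        self._jitter: np.ndarray | None = None
        # canonical parameter grid: cell-centred in theta (poles excluded),
        # periodic in phi
        nt, np_ = resolution, 2 * resolution
        self.theta_grid = (np.arange(nt) + 0.5) * math.pi / nt
        self.phi_grid = np.arange(np_) * 2 * math.pi / np_

    # -- radius field -------------------------------------------------------
    @staticmethod
    def template_radius(theta, phi):
        a, b, c = TEMPLATE_RADII
        st, ct = np.sin(theta), np.cos(theta)
        inv = np.sqrt(
            (st * np.cos(phi) / a) ** 2
            + (st * np.sin(phi) / b) ** 2
            + (ct / c) ** 2
        )
        r = 1.0 / inv
        septal = ((1 + np.cos(np.asarray(phi) - math.pi)) / 2) ** 2
        return r * (1.0 - CRESCENT_DEPTH * st ** 2 * septal)

    def radius(self, theta, phi):
        r = self.template_radius(theta, phi)
        for amp, fn in self._bumps:
            r = r + amp * fn(theta, phi)
        if self._noise is not None:
            r = r + self._noise(theta, phi)
        return r

    # -- derived geometry ---------------------------------------------------
    def _dense_angles(self, n: int = 96):
        th = (np.arange(n) + 0.5) * math.pi / n
        ph = np.arange(2 * n) * math.pi / n
        return np.meshgrid(th, ph, indexing="ij")

    def max_radius(self) -> float:
        th, ph = self._dense_angles()
        return float(self.radius(th, ph).max())

    def check_star_shaped(self) -> None:
        th, ph = self._dense_angles()
        rmin = float(self.radius(th, ph).min())
        if rmin <= 0:
            raise ValueError(
                f"deformation drives radius to {rmin:.3f} mm <= 0; "
                "amplitude too large for the template"
            )

    def volume(self, n: int = 192) -> float:
        """Enclosed volume by the divergence theorem:
        V = 1/3 * integral r^3 sin(theta) dtheta dphi."""
        th, ph = self._dense_angles(n)
        r = self.radius(th, ph)
        dt = math.pi / n
        dp = math.pi / n
        return float((r ** 3 * np.sin(th)).sum() * dt * dp / 3.0)

    def volume_centroid(self, n: int = 192) -> np.ndarray:
        """Centroid of the enclosed region (quadrature over the surface)."""
        th, ph = self._dense_angles(n)
        r = self.radius(th, ph)
        dt = dp = math.pi / n
        w = np.sin(th) * dt * dp
        unit = np.stack(
            [np.sin(th) * np.cos(ph), np.sin(th) * np.sin(ph), np.cos(th)],
            axis=-1,
        )
        v = (r ** 3 * w).sum() / 3.0
        c = (unit * (r ** 4 * w)[..., None]).sum(axis=(0, 1)) / 4.0
        return c / v

    # -- correspondence -----------------------------------------------------
    def gt_angles(self) -> tuple[np.ndarray, np.ndarray]:
        th, ph = np.meshgrid(self.theta_grid, self.phi_grid, indexing="ij")
        return th.ravel(), ph.ravel()

    def gt_correspondence(self) -> np.ndarray:
        """Canonical correspondence points, shape (n_theta * n_phi, 3), mm."""
        th, ph = self.gt_angles()
        r = self.radius(th, ph)
        pts = np.stack(
            [r * np.sin(th) * np.cos(ph), r * np.sin(th) * np.sin(ph),
             r * np.cos(th)],
            axis=1,
        )
        if self._jitter is not None:
            pts = pts + self._jitter
        return pts


def generate_base_surface(resolution: int = 24) -> GroundTruthShape:
    """Deterministic undeformed template (healthy reference geometry)."""
    return GroundTruthShape(resolution=resolution)


def apply_group_deformation(
    base: GroundTruthShape,
    group: str,
    subgroup: str,
    params: DeformationParams,
    rng: np.random.Generator,
    noise_sd: float = 0.0,
    landmark_jitter_sd: float = 0.0,
) -> GroundTruthShape:
    """Apply the group's deformation field plus subject-level noise.

    TR: outward free-wall bulge, apex blunting, base widening.
    Comorbid control: inward mid-free-wall displacement; the pHTN subgroup
    additionally narrows the mid-cavity ("streamlined" shape).
    Healthy: template plus noise only. Noise is added last.
    """
    if group not in GROUPS:
        raise ValueError(f"unknown group {group!r}")
    for a in (params.bulge_amp, params.apex_blunt_amp, params.base_width_amp,
              params.midwall_pinch_amp, params.streamline_amp):
        if not np.isfinite(a):
            raise ValueError("deformation amplitudes must be finite")
    out = GroundTruthShape(base.resolution, group, subgroup)
    if group == "tr":
        out._bumps.append((
            params.bulge_amp,
            lambda th, ph: _gauss_bump(th, ph, BULGE_CENTER, BULGE_WIDTH),
        ))
        out._bumps.append((
            params.apex_blunt_amp,
            lambda th, ph: np.exp(
                -((math.pi - np.asarray(th)) ** 2) / (2 * APEX_WIDTH ** 2)
            ),
        ))
        out._bumps.append((
            params.base_width_amp,
            lambda th, ph: np.exp(
                -((np.asarray(th) - BASE_CENTER) ** 2) / (2 * BASE_WIDTH ** 2)
            ),
        ))
    elif group == "control":
        out._bumps.append((
            -params.midwall_pinch_amp,
            lambda th, ph: _gauss_bump(th, ph, PINCH_CENTER, PINCH_WIDTH),
        ))
        if subgroup == "phtn":
            out._bumps.append((
                -params.streamline_amp,
                lambda th, ph: np.exp(
                    -((np.asarray(th) - math.pi / 2) ** 2)
                    / (2 * STREAMLINE_WIDTH ** 2)
                ),
            ))
    if noise_sd > 0:
        out._noise = _HarmonicField(noise_sd, rng)
    if landmark_jitter_sd > 0:
        n_pts = len(out.theta_grid) * len(out.phi_grid)
        out._jitter = rng.standard_normal((n_pts, 3)) * landmark_jitter_sd
    out.check_star_shaped()
    return out


def voxelize(
    shape: GroundTruthShape, spacing: float = 1.5, dims: int | tuple = 64
) -> SegmentationMask:
    """Rasterize: a voxel is foreground iff its center lies inside r(theta, phi).

    The grid is centred on the template origin. Raises if the shape does
    not fit with a two-voxel margin, or if the shape is thinner than a
    voxel (an empty rasterization is a contract violation, not a mask).
    """
    if np.isscalar(dims):
        dims = (int(dims),) * 3
    dims = tuple(int(d) for d in dims)
    rmax = shape.max_radius()
    if rmax < spacing / 2:
        raise ValueError(
            f"shape radius {rmax:.3f} mm is below half a voxel "
            f"({spacing / 2:.3f} mm); rasterization would be empty"
        )
    half_extent = (np.array(dims) - 1) / 2.0 * spacing
    required = rmax + 2 * spacing
    if np.any(half_extent < required):
        need = int(np.ceil(2 * required / spacing)) + 1
        raise ValueError(
            f"shape (max radius {rmax:.1f} mm) exceeds grid; "
            f"need dims >= {need} at spacing {spacing} mm"
        )
    origin = -half_extent
    ax = [origin[i] + np.arange(dims[i]) * spacing for i in range(3)]
    x, y, z = np.meshgrid(*ax, indexing="ij")
    rho = np.sqrt(x ** 2 + y ** 2 + z ** 2)
    with np.errstate(invalid="ignore", divide="ignore"):
        theta = np.arccos(np.clip(np.where(rho > 0, z / rho, 1.0), -1, 1))
    phi = np.arctan2(y, x)
    inside = rho < shape.radius(theta, phi)
    inside[rho == 0] = True
    return SegmentationMask(inside, np.full(3, float(spacing)), origin)


def _largest_remainder_counts(fractions: dict, total: int) -> dict:
    keys = sorted(fractions)
    raw = {k: fractions[k] * total for k in keys}
    counts = {k: int(math.floor(raw[k])) for k in keys}
    short = total - sum(counts.values())
    by_rem = sorted(keys, key=lambda k: (-(raw[k] - counts[k]), k))
    for k in by_rem[:short]:
        counts[k] += 1
    return counts


@dataclass
class CohortSubject:
    subject_id: str
    group: str
    subgroup: str
    shape: GroundTruthShape
    mask: SegmentationMask | None


def generate_cohort(
    spec: CohortSpec, with_masks: bool = True
) -> tuple[list[CohortSubject], pd.DataFrame]:
    """Generate the full cohort, deterministically from ``spec.seed``.

    Returns the subjects (ground truth plus, unless ``with_masks=False``,
    the voxelized segmentation) and a manifest table.
    """
    spec.validate()
    base = generate_base_surface(spec.gt_resolution)
    ss = np.random.SeedSequence(spec.seed)
    subjects: list[CohortSubject] = []
    rows = []
    idx = 0
    for group in GROUPS:
        n = spec.group_sizes.get(group, 0)
        if n == 0:
            continue
        fracs = spec.subgroup_fractions.get(group, {"none": 1.0})
        counts = _largest_remainder_counts(fracs, n)
        tags = [sg for sg in sorted(counts) for _ in range(counts[sg])]
        for sg in tags:
            rng = np.random.default_rng(ss.spawn(1)[0])
            shape = apply_group_deformation(
                base, group, sg, spec.deformation_params, rng,
                noise_sd=spec.noise_sd,
                landmark_jitter_sd=spec.landmark_jitter_sd,
            )
            mask = None
            if with_masks:
                mask = voxelize(shape, spec.voxel_spacing, spec.grid_dims)
                mask.subject_id = f"s{idx:03d}"
            subjects.append(
                CohortSubject(f"s{idx:03d}", group, sg, shape, mask)
            )
            rows.append({
                "subject_id": f"s{idx:03d}", "group": group, "subgroup": sg,
                "seed": spec.seed,
            })
            idx += 1
    manifest = pd.DataFrame(
        rows, columns=["subject_id", "group", "subgroup", "seed"]
    )
    return subjects, manifest


def check_single_component(mask: SegmentationMask) -> bool:
    """True when the foreground is one 6-connected component."""
    structure = ndimage.generate_binary_structure(3, 1)
    _, n = ndimage.label(mask.voxels, structure=structure)
    return n == 1


def write_cohort(
    subjects: list[CohortSubject],
    manifest: pd.DataFrame,
    outdir,
    mask_format: str = "nifti",
) -> pd.DataFrame:
    """Write masks, ground-truth .particles files and the manifest CSV."""
    import os

    from . import particle_correspondence as pc
    from .volume_preprocess import write_mask_metaimage, write_mask_nifti

    os.makedirs(outdir, exist_ok=True)
    files = []
    for subj in subjects:
        if subj.mask is None:
            files.append("")
        elif mask_format == "nifti":
            path = os.path.join(outdir, f"{subj.subject_id}.nii.gz")
            write_mask_nifti(subj.mask, path)
            files.append(path)
        elif mask_format == "metaimage":
            path = os.path.join(outdir, f"{subj.subject_id}.mhd")
            write_mask_metaimage(subj.mask, path)
            files.append(path)
        else:
            raise ValueError(f"unknown mask format {mask_format!r}")
        pc.write_particle_file(
            subj.shape.gt_correspondence(),
            os.path.join(outdir, f"{subj.subject_id}.particles"),
        )
    out = manifest.copy()
    out["file"] = files
    out.to_csv(os.path.join(outdir, "manifest.csv"), index=False)
    return out
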