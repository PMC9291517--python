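"""Particle-based correspondence across a shape cohort.

Places M ordered particles on every subject's surface (the zero level set
of its signed distance transform) by gradient descent on a two-term
objective:

* a per-shape **sampling** term — Gaussian-kernel pairwise repulsion
  energy, whose minimization spreads particles uniformly over each
  surface; and
* a cross-cohort **correspondence** term — the log-determinant of the
  (regularized) covariance of the stacked particle-coordinate vectors,
  whose minimization makes the cohort's particle configurations
  statistically compact, i.e. index j lands on the analogous location on
  every subject.

The particle count grows by a splitting schedule 1 -> 2 -> ... -> M (each
split duplicates every particle with a small shared random offset and
reprojects), the standard construction of particle-based shape modeling.
Steps are accepted only when they do not increase the objective
(backtracking halving), so the objective is non-increasing within a stage
by construction.
"""

from __future__ import annotations

import os
import re
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import map_coordinates

from .volume_preprocess import DistanceTransform

#: surface tolerance as a multiple of voxel spacing
TOL_SURF_FACTOR = 0.5

_MAX_PROJECT_ITER = 20


@dataclass
class ParticleSystem:
    """Ordered correspondence particles, shape (K subjects, M, 3), mm."""

    points: np.ndarray
    subject_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 3 or self.points.shape[2] != 3:
            raise ValueError("points must have shape (K, M, 3)")
        if not self.subject_ids:
            self.subject_ids = [f"s{i:03d}" for i in range(self.points.shape[0])]
        if len(self.subject_ids) != self.points.shape[0]:
            raise ValueError("subject_ids length must match K")

    @property
    def n_subjects(self) -> int:
        return self.points.shape[0]

    @property
    def n_particles(self) -> int:
        return self.points.shape[1]

    def flatten(self) -> np.ndarray:
        """(K, 3M) matrix in (x1, y1, z1, ..., xM, yM, zM) order."""
        return self.points.reshape(self.n_subjects, -1)


@dataclass
class OptimizerConfig:
    M: int = 512
    iterations_per_split: int = 40
    step_size: float = 1.0
    # kernel bandwidth as a multiple of each particle's NN distance; must
    # stay below ~0.7, where the Gaussian pair potential starts to favour
    # particle merging over uniform spread
    sigma_factor: float = 0.6
    alpha: float = 0.5
    seed: int = 0
    tol_surf: float | None = None  # default 0.5 * spacing
    covariance_eps: float = 1e-2  # mm^2 ridge on the cohort covariance

    def validate(self) -> None:
        if self.M < 1:
            raise ValueError("M must be >= 1")
        if self.step_size <= 0:
            raise ValueError("step_size must be positive")
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must lie in [0, 1]")


# ---------------------------------------------------------------------------
# Distance-field interpolation and surface projection
# ---------------------------------------------------------------------------

class _DTField:
    """Trilinear interpolation of a DT and its central-difference gradient."""

    def __init__(self, dt: DistanceTransform):
        self.dt = dt
        self.values = dt.values.astype(float)
        g = np.gradient(self.values, dt.spacing)
        self.grad = np.stack(g, axis=0)

    def d(self, pts: np.ndarray) -> np.ndarray:
        idx = self.dt.world_to_index(pts).T
        return map_coordinates(self.values, idx, order=1, mode="nearest")

    def grad_d(self, pts: np.ndarray) -> np.ndarray:
        idx = self.dt.world_to_index(pts).T
        return np.stack(
            [map_coordinates(self.grad[a], idx, order=1, mode="nearest")
             for a in range(3)],
            axis=1,
        )

    def in_bounds(self, pts: np.ndarray) -> np.ndarray:
        idx = self.dt.world_to_index(pts)
        upper = np.array(self.dt.shape) - 1
        return np.all((idx >= 0) & (idx <= upper), axis=1)


def project_to_surface(
    point: np.ndarray, dt: DistanceTransform, tol_surf: float | None = None
) -> np.ndarray:
    """Project a point onto the DT zero level set by Newton steps
    ``x <- x - D(x) * grad(D)/|grad(D)|^2`` until ``|D| < tol_surf``."""
    field_ = dt if isinstance(dt, _DTField) else _DTField(dt)
    pts = np.atleast_2d(np.asarray(point, dtype=float))
    out = _project_batch(pts, field_, tol_surf)
    return out[0] if np.asarray(point).ndim == 1 else out


def _project_batch(
    pts: np.ndarray, field_: _DTField, tol_surf: float | None
) -> np.ndarray:
    tol = (TOL_SURF_FACTOR * field_.dt.spacing) if tol_surf is None else tol_surf
    pts = np.array(pts, dtype=float)
    if not np.all(field_.in_bounds(pts)):
        raise ValueError("point outside the distance-transform grid")
    lo = field_.dt.origin
    hi = field_.dt.origin + (np.array(field_.dt.shape) - 1) * field_.dt.spacing
    active = np.abs(field_.d(pts)) >= tol
    for _ in range(_MAX_PROJECT_ITER):
        if not active.any():
            break
        sub = pts[active]
        d = field_.d(sub)
        g = field_.grad_d(sub)
        # x <- x - D(x) * grad(D)/|grad(D)|, with the gradient norm clamped
        # away from zero (it vanishes on the medial axis)
        gnorm = np.maximum(np.linalg.norm(g, axis=1), 0.2)
        cand = sub - (d / gnorm)[:, None] * g
        pts[active] = np.clip(cand, lo, hi)
        active = np.abs(field_.d(pts)) >= tol
    if active.any():
        resid = float(np.abs(field_.d(pts[active])).max())
        raise RuntimeError(
            f"surface projection failed to converge within "
            f"{_MAX_PROJECT_ITER} iterations (max residual {resid:.4f} mm)"
        )
    return pts


# ---------------------------------------------------------------------------
# Objective terms
# ---------------------------------------------------------------------------

def _sampling_energy_and_force(x: np.ndarray, sigma):
    """Gaussian-kernel repulsion energy and its negative gradient.

    E = sum_i sum_{j != i} exp(-|xi-xj|^2 / (2 sigma_i^2)): a pairwise
    kernel overlap whose minimization spreads the particles uniformly.
    Coincident particles always carry maximal energy, so merging is never
    favourable. ``sigma`` may be a scalar or a per-particle vector —
    per-particle bandwidths keep the repulsion gradient strong for
    crowded particles, where a single global bandwidth leaves it
    vanishing.
    """
    m = len(x)
    if m < 2:
        return 0.0, np.zeros_like(x)
    sig = np.broadcast_to(np.asarray(sigma, dtype=float), (m,))
    diff = x[:, None, :] - x[None, :, :]
    d2 = (diff ** 2).sum(axis=2)
    w = np.exp(-d2 / (2 * sig[:, None] ** 2))  # row i uses sigma_i
    np.fill_diagonal(w, 0.0)
    energy = float(w.sum())
    # force = -dE/dx: own-row term plus each neighbour's row term
    coef = w / sig[:, None] ** 2
    coef = coef + coef.T
    f = (coef[:, :, None] * diff).sum(axis=1)
    return energy, f


def _correspondence_energy_and_grad(points: np.ndarray, eps: float):
    """log det of the regularized cohort covariance (dual K x K form)
    and its gradient with respect to the particle coordinates."""
    k = points.shape[0]
    z = points.reshape(k, -1)
    y = z - z.mean(axis=0, keepdims=True)
    g = y @ y.T / (k - 1)
    gi = np.linalg.inv(g + eps * np.eye(k))
    sign, logdet = np.linalg.slogdet(g + eps * np.eye(k))
    grad_y = 2.0 / (k - 1) * (gi @ y)
    grad_y = grad_y - grad_y.mean(axis=0, keepdims=True)
    return float(logdet), grad_y.reshape(points.shape)


def _ray_march_init(field_: _DTField, spacing: float,
                    tol: float) -> np.ndarray:
    """Deterministic first-particle seed: the +z surface crossing from
    the grid center, tightened by projection."""
    center = field_.dt.index_to_world(
        (np.array(field_.dt.shape) - 1) / 2.0
    )[0]
    zmax = field_.dt.origin[2] \
        + (field_.dt.shape[2] - 1) * field_.dt.spacing
    lo = center.copy()
    d_lo = field_.d(lo[None, :])[0]
    hi = None
    steps = int((zmax - center[2]) / (0.25 * spacing))
    for k in range(1, max(steps, 2)):
        p = center + np.array([0.0, 0.0, 0.25 * spacing * k])
        if p[2] > zmax:
            break
        if field_.d(p[None, :])[0] >= 0:
            hi = p
            break
        lo = p
    if hi is None:
        hi = np.array([center[0], center[1], zmax])
    for _ in range(30):  # bisect the crossing
        mid = (lo + hi) / 2.0
        if field_.d(mid[None, :])[0] < 0:
            lo = mid
        else:
            hi = mid
    return _project_batch(((lo + hi) / 2.0)[None, :], field_, tol)[0]


def _mean_nn_distance(x: np.ndarray) -> float:
    if len(x) < 2:
        return 1.0
    diff = x[:, None, :] - x[None, :, :]
    d = np.sqrt((diff ** 2).sum(axis=2))
    np.fill_diagonal(d, np.inf)
    return float(d.min(axis=1).mean())


def _objective(points, fields, sigmas, alpha, eps):
    samp = 0.0
    for k, f in enumerate(fields):
        e, _ = _sampling_energy_and_force(points[k], sigmas[k])
        samp += e
    if alpha > 0 and len(fields) >= 2:
        corr, _ = _correspondence_energy_and_grad(points, eps)
    else:
        corr = 0.0
    return alpha * corr + (1 - alpha) * samp


def _stage_sigmas(points, factor, spacing):
    """Per-particle kernel bandwidths from current NN spacing, (K, m)."""
    k, m, _ = points.shape
    if m < 2:
        return np.full((k, m), max(spacing, 1.0))
    out = np.empty((k, m))
    for i in range(k):
        x = points[i]
        d = np.sqrt(((x[:, None] - x[None, :]) ** 2).sum(axis=2))
        np.fill_diagonal(d, np.inf)
        out[i] = factor * d.min(axis=1)
    return np.maximum(out, 0.25 * spacing)


# ---------------------------------------------------------------------------
# Main optimization
# ---------------------------------------------------------------------------

def optimize_particles(
    dts: list[DistanceTransform], config: OptimizerConfig | None = None
) -> tuple[ParticleSystem, list[np.ndarray]]:
    """Distribute ``config.M`` corresponding particles on every DT surface.

    Returns the particle system and the per-stage objective traces (the
    last trace covers the final particle count; it is non-increasing).
    Deterministic given ``config.seed``.
    """
    config = config or OptimizerConfig()
    config.validate()
    if len(dts) < 1:
        raise ValueError("optimize_particles requires at least one DT")
    shapes = {d.values.shape for d in dts}
    spacings = {round(d.spacing, 9) for d in dts}
    if len(shapes) > 1 or len(spacings) > 1:
        raise ValueError("all distance transforms must share one grid")
    spacing = dts[0].spacing
    tol = config.tol_surf if config.tol_surf is not None \
        else TOL_SURF_FACTOR * spacing
    alpha = config.alpha if len(dts) >= 2 else 0.0

    fields = [_DTField(d) for d in dts]
    rng = np.random.default_rng(config.seed)

    # initial particle: march from the grid center along +z to the first
    # surface crossing (projection from deep inside, near the medial
    # axis, would land on arbitrary sides of the shape per subject)
    points = np.stack([
        _ray_march_init(f, spacing, tol)[None, :] for f in fields
    ])

    traces: list[np.ndarray] = []
    stage = 0
    while True:
        m = points.shape[1]
        stage_alpha = 0.0 if stage == 0 else alpha
        # three sub-stages per level: the per-particle kernel bandwidths
        # follow the growing inter-particle spacing, and the final
        # sub-stage runs at frozen bandwidths (so its objective is
        # exactly non-increasing)
        stage_trace = []
        for _ in range(3 if m > 1 else 1):
            sigmas = _stage_sigmas(points, config.sigma_factor, spacing)
            stage_trace = _descend(points, fields, sigmas, stage_alpha,
                                   config, tol)
        traces.append(stage_trace)
        if m >= config.M:
            break
        # split: duplicate with a shared random offset projected onto each
        # surface's tangent plane (a normal offset would collapse the
        # child back onto its parent), then reproject
        n_new = min(m, config.M - m)
        offsets = rng.standard_normal((n_new, 3))
        offsets /= np.linalg.norm(offsets, axis=1, keepdims=True)
        new_pts = []
        for k in range(len(fields)):
            parents = points[k, :n_new]
            normals = fields[k].grad_d(parents)
            normals /= np.maximum(
                np.linalg.norm(normals, axis=1, keepdims=True), 1e-12)
            tang = offsets - (offsets * normals).sum(axis=1,
                                                     keepdims=True) * normals
            norm = np.linalg.norm(tang, axis=1, keepdims=True)
            # fall back to a fixed tangent recipe where offset ~ normal
            bad = norm[:, 0] < 0.1
            if bad.any():
                alt = np.cross(normals[bad], np.array([0.731, 0.327, 0.601]))
                tang[bad] = alt
                norm = np.linalg.norm(tang, axis=1, keepdims=True)
            tang *= (0.5 * spacing) / np.maximum(norm, 1e-12)
            children = _project_batch(parents + tang, fields[k], tol)
            new_pts.append(np.concatenate([points[k], children], axis=0))
        points = np.stack(new_pts)
        stage += 1

    for k, f in enumerate(fields):
        if not np.all(f.in_bounds(points[k])):
            j = int(np.where(~f.in_bounds(points[k]))[0][0])
            raise RuntimeError(
                f"particle {j} escaped the grid on subject {k}"
            )
    return ParticleSystem(points), traces


def _descend(points, fields, sigmas, alpha, config, tol) -> np.ndarray:
    """In-place accept-only-decrease gradient descent for one sub-stage."""
    eps = config.covariance_eps
    k_subj = len(fields)
    obj = _objective(points, fields, sigmas, alpha, eps)
    trace = [obj]
    step = config.step_size  # dimensionless: directions carry mm scale
    for _ in range(config.iterations_per_split):
        # descent direction
        direction = np.zeros_like(points)
        for k in range(k_subj):
            _, force = _sampling_energy_and_force(points[k], sigmas[k])
            direction[k] += (1 - alpha) * force
        if alpha > 0 and k_subj >= 2:
            _, cgrad = _correspondence_energy_and_grad(points, eps)
            direction -= alpha * cgrad
        # project direction onto surface tangent planes
        for k in range(k_subj):
            n = fields[k].grad_d(points[k])
            n /= np.maximum(np.linalg.norm(n, axis=1, keepdims=True), 1e-12)
            direction[k] -= (direction[k] * n).sum(axis=1, keepdims=True) * n
        dnorm = np.linalg.norm(direction, axis=2, keepdims=True)
        if dnorm.max() < 1e-14:
            trace.append(obj)
            continue
        # per-particle scaling: each particle steps along its own force at
        # a pace set by its local bandwidth (forces span orders of
        # magnitude under adaptive bandwidths, and a global normalization
        # would freeze all but the most crowded particle)
        scale = np.minimum(dnorm, sigmas[..., None] * 0.5)
        direction = np.where(dnorm > 1e-14, direction / np.maximum(
            dnorm, 1e-30) * scale, 0.0)
        tau = step
        accepted = False
        for _ in range(8):
            cand = points + tau * direction
            try:
                cand = np.stack([
                    _project_batch(cand[k], fields[k], tol)
                    for k in range(k_subj)
                ])
            except (RuntimeError, ValueError):
                tau *= 0.5
                continue
            new_obj = _objective(cand, fields, sigmas, alpha, eps)
            if new_obj <= obj + 1e-12:
                points[...] = cand
                obj = new_obj
                accepted = True
                break
            tau *= 0.5
        trace.append(obj)
        if not accepted:
            step *= 0.5  # shrink the base step when stuck
    return np.asarray(trace)


# ---------------------------------------------------------------------------
# Ground-truth bypass
# ---------------------------------------------------------------------------

def farthest_point_indices(points: np.ndarray, m: int,
                           start: int | None = None) -> np.ndarray:
    """Deterministic greedy farthest-point subsample of a point set.

    The greedy walk starts at the point with maximal z (the apex-pole
    sample on the canonical template grid) unless ``start`` is given.
    """
    n = len(points)
    if m > n:
        raise ValueError(f"cannot select {m} of {n} points")
    if start is None:
        start = int(np.argmin(points[:, 2]))
    chosen = [start]
    dist = np.linalg.norm(points - points[start], axis=1)
    for _ in range(m - 1):
        nxt = int(np.argmax(dist))
        chosen.append(nxt)
        dist = np.minimum(dist, np.linalg.norm(points - points[nxt], axis=1))
    return np.asarray(chosen)


def attach_ground_truth(shapes, m: int = 512,
                        subject_ids: list[str] | None = None,
                        center: bool = True) -> ParticleSystem:
    """Build a ParticleSystem from the generator's exact correspondences.

    Subsamples the canonical parameter grid to ``m`` points by
    farthest-point selection **on the template mean geometry**, so the
    same grid indices are used for every subject. With ``center=True``
    each subject is translated by its analytic volume centroid, matching
    the frame produced by centroid alignment of the voxelized masks.
    """
    gts = [s.gt_correspondence() for s in shapes]
    n_pts = {g.shape[0] for g in gts}
    if len(n_pts) != 1:
        raise ValueError("ground truths are not index-consistent")
    template = np.mean(gts, axis=0)
    idx = farthest_point_indices(template, m)
    pts = []
    for s, g in zip(shapes, gts):
        p = g[idx]
        if center:
            p = p - s.volume_centroid()
        pts.append(p)
    return ParticleSystem(np.stack(pts), subject_ids or [])


# ---------------------------------------------------------------------------
# .particles file I/O (one "x y z" line per particle)
# ---------------------------------------------------------------------------

def write_particle_file(points: np.ndarray, path: str) -> None:
    points = np.asarray(points, dtype=float)
    if points.ndim != 2 or points.shape[1] != 3:
        raise ValueError("points must have shape (M, 3)")
    np.savetxt(path, points, fmt="%.6f")


def read_particle_file(path: str, expected_m: int | None = None) -> np.ndarray:
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            parts = re.split(r"\s+", line.strip())
            if len(parts) != 3:
                raise ValueError(
                    f"{path}:{lineno}: expected 3 columns, got {len(parts)}"
                )
            try:
                rows.append([float(p) for p in parts])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from None
    if expected_m is not None and len(rows) != expected_m:
        raise ValueError(
            f"{path}: expected {expected_m} particles, found {len(rows)}"
        )
    return np.asarray(rows, dtype=float)


def write_particles(system: ParticleSystem, outdir: str) -> list[str]:
    os.makedirs(outdir, exist_ok=True)
    paths = []
    for sid, pts in zip(system.subject_ids, system.points):
        path = os.path.join(outdir, f"{sid}.particles")
        write_particle_file(pts, path)
        paths.append(path)
    return paths


def read_particles(paths: list[str],
                   expected_m: int | None = None) -> ParticleSystem:
    pts = [read_particle_file(p, expected_m) for p in paths]
    m = {len(p) for p in pts}
    if len(m) != 1:
        raise ValueError("particle files have inconsistent particle counts")
    ids = [os.path.splitext(os.path.basename(p))[0] for p in paths]
    return ParticleSystem(np.stack(pts), ids)
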