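"""Group-level shape statistics.

Two complementary views of a two-group shape difference:

* **Linear discrimination of variation (LDV).** The difference vector
  between the two group mean shapes defines a direction in shape space;
  projecting every subject onto it by dot product yields a scalar
  shape-based score. The two group-mean projections are affinely
  rescaled to -1 (group A, by convention the TR-bearing group) and +1
  (group B), all other subjects follow the same affine map, and a
  univariate Gaussian is fitted per group to the normalized scores.

* **Per-point Hotelling T-squared maps.** At each correspondence point
  the two groups' 3-D coordinate clouds are compared with the two-sample
  Hotelling T^2 statistic; p-values come from its F(3, n1+n2-4)
  transform, Benjamini-Hochberg FDR adjustment controls the discovery
  rate across the M points, and adjusted p < 0.05 marks a point
  significant. The pooled covariance carries a small ridge so points
  with (near-)degenerate scatter remain well defined.

Scores are computed on centered data; centering shifts every raw score by
the same constant, which the +/-1 affine normalization absorbs, so the
normalized scores are unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .particle_correspondence import ParticleSystem
from .shape_space import ShapeMatrix

#: ridge added to the pooled per-point covariance, mm^2
COV_RIDGE = 1e-6

ALPHA_LEVEL = 0.05


@dataclass
class LDVResult:
    d: np.ndarray                   # group-mean difference vector (3M,)
    mu_A: np.ndarray
    mu_B: np.ndarray
    raw_scores: np.ndarray          # per subject
    norm_scores: np.ndarray
    subject_ids: list
    group3: np.ndarray | None
    in_A: np.ndarray                # boolean masks of the two groups
    in_B: np.ndarray
    gauss_A: tuple                  # (mean, sd) of normalized scores
    gauss_B: tuple

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({
            "subject_id": self.subject_ids,
            "raw_score": self.raw_scores,
            "norm_score": self.norm_scores,
            "in_group_A": self.in_A,
            "in_group_B": self.in_B,
        })
        if self.group3 is not None:
            df["group"] = self.group3
        return df


@dataclass
class SignificanceMap:
    t2: np.ndarray
    p_raw: np.ndarray
    p_adj: np.ndarray
    significant: np.ndarray
    group_sizes: tuple

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "point": np.arange(len(self.t2)),
            "t2": self.t2,
            "p_raw": self.p_raw,
            "p_adj": self.p_adj,
            "significant": self.significant,
        })


def ldv_scores(matrix: ShapeMatrix, group_A, group_B) -> LDVResult:
    """Linear-discrimination shape scores, normalized to -1/+1 group means.

    ``group_A`` maps to -1 and ``group_B`` to +1; pass the TR-bearing
    group as A to follow the reporting convention.
    """
    mask_a = matrix.group_mask(group_A)
    mask_b = matrix.group_mask(group_B)
    if mask_a.sum() == 0 or mask_b.sum() == 0:
        raise ValueError("both groups must be non-empty")
    if np.any(mask_a & mask_b):
        raise ValueError("groups overlap")
    mu_a = matrix.X[mask_a].mean(axis=0)
    mu_b = matrix.X[mask_b].mean(axis=0)
    d = mu_b - mu_a
    if np.linalg.norm(d) == 0:
        raise ValueError("group mean shapes are identical; no direction "
                         "to normalize")
    center = matrix.X.mean(axis=0)
    raw = (matrix.X - center) @ d
    ra = (mu_a - center) @ d
    rb = (mu_b - center) @ d
    # affine map sending ra -> -1, rb -> +1 (strictly monotone: rb-ra=|d|^2>0)
    norm = -1.0 + 2.0 * (raw - ra) / (rb - ra)
    ga = (float(norm[mask_a].mean()), float(norm[mask_a].std()))
    gb = (float(norm[mask_b].mean()), float(norm[mask_b].std()))
    return LDVResult(d, mu_a, mu_b, raw, norm, list(matrix.subject_ids),
                     matrix.group3, mask_a, mask_b, ga, gb)


def overlap_fraction(result: LDVResult) -> float:
    """Fraction of scored group members inside the score-range intersection.

    The overlap region is [max of the two group minima, min of the two
    group maxima]; disjoint ranges give 0. This is an explicit
    interpretation of "overlapping region" — a range-based one.
    """
    a = result.norm_scores[result.in_A]
    b = result.norm_scores[result.in_B]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("both groups need >= 2 scored members")
    lo = max(a.min(), b.min())
    hi = min(a.max(), b.max())
    if lo > hi:
        return 0.0
    scores = np.concatenate([a, b])
    return float(np.mean((scores >= lo) & (scores <= hi)))


def hotelling_map(particles: ParticleSystem, labels, group_A, group_B,
                  alpha: float = ALPHA_LEVEL) -> SignificanceMap:
    """Per-correspondence-point two-sample Hotelling T^2 with BH-FDR.

    T^2 = (n1*n2/(n1+n2)) * (m1-m2)' S_pooled^-1 (m1-m2) on each point's
    3-D coordinates; p from the exact F(3, n1+n2-4) transform.
    """
    labels = np.asarray(labels)
    x1 = particles.points[labels == group_A]
    x2 = particles.points[labels == group_B]
    n1, n2 = len(x1), len(x2)
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs at least two subjects")
    n = n1 + n2
    if n < 5:
        raise ValueError("n1 + n2 must be >= 5 for the F transform")
    p_dim = 3
    m1 = x1.mean(axis=0)
    m2 = x2.mean(axis=0)
    diff = m1 - m2                                        # (M, 3)
    c1 = np.einsum("kmi,kmj->mij", x1 - m1, x1 - m1)
    c2 = np.einsum("kmi,kmj->mij", x2 - m2, x2 - m2)
    pooled = (c1 + c2) / (n - 2) + COV_RIDGE * np.eye(p_dim)
    m_pts = particles.n_particles
    t2 = np.empty(m_pts)
    ok = np.ones(m_pts, dtype=bool)
    for j in range(m_pts):
        try:
            sol = np.linalg.solve(pooled[j], diff[j])
            t2[j] = (n1 * n2 / n) * float(diff[j] @ sol)
        except np.linalg.LinAlgError:
            t2[j] = 0.0
            ok[j] = False
    f_stat = t2 * (n - p_dim - 1) / ((n - 2) * p_dim)
    p_raw = stats.f.sf(f_stat, p_dim, n - p_dim - 1)
    p_raw[~ok] = 1.0
    reject, p_adj, _, _ = multipletests(p_raw, alpha=alpha, method="fdr_bh")
    return SignificanceMap(t2, p_raw, p_adj, reject, (n1, n2))


def hotelling_map_permutation(particles: ParticleSystem, labels, group_A,
                              group_B, n_perm: int = 1000, seed: int = 0,
                              alpha: float = ALPHA_LEVEL) -> SignificanceMap:
    """Permutation-null alternative for small groups: per-point p-values
    from label shuffles of the T^2 statistic, then BH-FDR."""
    labels = np.asarray(labels)
    sel = (labels == group_A) | (labels == group_B)
    pts = ParticleSystem(particles.points[sel],
                         [s for s, m in zip(particles.subject_ids, sel) if m])
    lab = labels[sel]
    obs = hotelling_map(pts, lab, group_A, group_B, alpha)
    rng = np.random.default_rng(seed)
    exceed = np.zeros(pts.n_particles)
    for _ in range(n_perm):
        perm = rng.permutation(lab)
        t2p = hotelling_map(pts, perm, group_A, group_B, alpha).t2
        exceed += t2p >= obs.t2
    p_raw = (exceed + 1) / (n_perm + 1)
    reject, p_adj, _, _ = multipletests(p_raw, alpha=alpha, method="fdr_bh")
    return SignificanceMap(obs.t2, p_raw, p_adj, reject, obs.group_sizes)


def mean_difference_arrows(matrix: ShapeMatrix, group_A, group_B):
    """Per-point displacement mean(B) - mean(A) and its magnitudes."""
    mask_a = matrix.group_mask(group_A)
    mask_b = matrix.group_mask(group_B)
    if mask_a.sum() == 0 or mask_b.sum() == 0:
        raise ValueError("both groups must be non-empty")
    d = matrix.X[mask_b].mean(axis=0) - matrix.X[mask_a].mean(axis=0)
    arrows = d.reshape(-1, 3)
    mags = np.linalg.norm(arrows, axis=1)
    return arrows, mags


def arrows_frame(arrows: np.ndarray, mags: np.ndarray,
                 sig: SignificanceMap | None = None) -> pd.DataFrame:
    df = pd.DataFrame({
        "point": np.arange(len(arrows)),
        "dx": arrows[:, 0], "dy": arrows[:, 1], "dz": arrows[:, 2],
        "magnitude": mags,
    })
    if sig is not None:
        for col in ("t2", "p_raw", "p_adj", "significant"):
            df[col] = getattr(sig, col)
    return df
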