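"""LDV shape scores, overlap fractions and Hotelling significance maps."""

import numpy as np
import pytest

from rvshape import group_statistics as gs
from rvshape import synthetic_cohort as sc
from rvshape.particle_correspondence import ParticleSystem, \
    attach_ground_truth
from rvshape.shape_space import ShapeMatrix


def two_group_matrix(n_a=4, n_b=4, dim=12, sep=3.0, seed=0):
    rng = np.random.default_rng(seed)
    xa = rng.normal(size=(n_a, dim))
    xb = rng.normal(size=(n_b, dim)) + sep / np.sqrt(dim)
    g = np.array(["tr"] * n_a + ["control"] * n_b)
    return ShapeMatrix(np.vstack([xa, xb]), group3=g)


class TestLDV:
    def test_group_means_map_to_plus_minus_one(self):
        m = two_group_matrix()
        res = gs.ldv_scores(m, "tr", "control")
        mu_a_score = res.norm_scores[res.in_A]
        # score of the mean equals mean of scores (linearity)
        assert mu_a_score.mean() == pytest.approx(-1.0, abs=1e-10)
        assert res.norm_scores[res.in_B].mean() == pytest.approx(
            1.0, abs=1e-10)

    def test_midpoint_subject_scores_zero(self):
        m = two_group_matrix(dim=6)
        mid = (m.X[m.group3 == "tr"].mean(axis=0)
               + m.X[m.group3 == "control"].mean(axis=0)) / 2
        m2 = ShapeMatrix(np.vstack([m.X, mid]),
                         group3=np.append(m.group3, "healthy"))
        res = gs.ldv_scores(m2, "tr", "control")
        assert res.norm_scores[-1] == pytest.approx(0.0, abs=1e-10)

    def test_hand_computed_toy_example(self):
        # 3M = 6, integer coordinates, two subjects per group
        a1 = np.array([0.0, 0, 0, 0, 0, 0])
        a2 = np.array([2.0, 0, 0, 0, 0, 0])
        b1 = np.array([4.0, 0, 0, 2, 0, 0])
        b2 = np.array([6.0, 0, 0, -2, 0, 0])
        m = ShapeMatrix(np.vstack([a1, a2, b1, b2]),
                        group3=np.array(["tr", "tr", "control", "control"]))
        res = gs.ldv_scores(m, "tr", "control")
        # d = muB - muA = (4, 0, 0, 0, 0, 0); raw scores on centred rows:
        # x-centre = 3 -> raw = (-12, -4, 4, 12); muA raw = -8, muB raw = 8
        assert np.allclose(res.d, [4, 0, 0, 0, 0, 0])
        assert np.allclose(res.raw_scores, [-12, -4, 4, 12], atol=1e-10)
        assert np.allclose(res.norm_scores, [-1.5, -0.5, 0.5, 1.5],
                           atol=1e-10)

    def test_identical_means_error(self):
        x = np.array([[1.0, 2, 3], [1.0, 2, 3]])
        m = ShapeMatrix(np.hstack([x, x]),
                        group3=np.array(["tr", "control"]))
        with pytest.raises(ValueError, match="identical"):
            gs.ldv_scores(m, "tr", "control")

    def test_translation_invariance(self):
        m = two_group_matrix(dim=9)
        res_a = gs.ldv_scores(m, "tr", "control")
        shift = np.tile([5.0, -3.0, 2.0], 3)
        m2 = ShapeMatrix(m.X + shift, group3=m.group3)
        res_b = gs.ldv_scores(m2, "tr", "control")
        assert np.allclose(res_a.norm_scores, res_b.norm_scores,
                           atol=1e-9)

    def test_separation_grows_with_bulge_amplitude(self):
        """Standardized raw-score separation increases with the
        TR bulge amplitude (1x, 3x, 5x the noise sd)."""
        seps = []
        for mult in (1.0, 3.0, 5.0):
            spec = sc.CohortSpec(
                group_sizes={"control": 10, "tr": 10},
                deformation_params=sc.DeformationParams(
                    bulge_amp=mult * 1.0, apex_blunt_amp=0.0,
                    base_width_amp=0.0, midwall_pinch_amp=0.0),
                noise_sd=1.0, seed=3,
            )
            subs, man = sc.generate_cohort(spec, with_masks=False)
            system = attach_ground_truth([s.shape for s in subs], m=128)
            matrix = ShapeMatrix.from_particles(
                system, group3=man["group"].to_numpy())
            res = gs.ldv_scores(matrix, "tr", "control")
            a = res.raw_scores[res.in_A]
            b = res.raw_scores[res.in_B]
            pooled = np.sqrt((a.var(ddof=1) + b.var(ddof=1)) / 2)
            seps.append(abs(a.mean() - b.mean()) / pooled)
        assert seps[0] < seps[1] < seps[2]


class TestOverlap:
    def test_identical_distributions_full_overlap(self):
        scores = np.array([-1.0, -0.5, 0.5, 1.0] * 2)
        res = _ldv_stub(scores, np.array([True] * 4 + [False] * 4))
        assert gs.overlap_fraction(res) == 1.0

    def test_disjoint_ranges_zero(self):
        scores = np.array([-1.0, -0.5, 0.5, 1.0])
        res = _ldv_stub(scores, np.array([True, True, False, False]))
        assert gs.overlap_fraction(res) == 0.0

    def test_enumerated_half_overlap(self):
        scores = np.array([-1.0, -0.2, -0.4, 1.0])
        res = _ldv_stub(scores, np.array([True, True, False, False]))
        assert gs.overlap_fraction(res) == pytest.approx(0.5)


def _ldv_stub(norm_scores, in_a):
    return gs.LDVResult(
        d=np.ones(3), mu_A=np.zeros(3), mu_B=np.ones(3),
        raw_scores=norm_scores, norm_scores=norm_scores,
        subject_ids=[f"s{i}" for i in range(len(norm_scores))],
        group3=None, in_A=in_a, in_B=~in_a,
        gauss_A=(0, 1), gauss_B=(0, 1),
    )


def jittered_null_system(n=20, m=64, seed=0):
    """Null cohort: one group, radial noise plus 3-D landmark jitter."""
    spec = sc.CohortSpec(
        group_sizes={"healthy": n, "control": 0, "tr": 0},
        noise_sd=1.0, landmark_jitter_sd=0.5, gt_resolution=16, seed=seed,
    )
    subs, _ = sc.generate_cohort(spec, with_masks=False)
    pts = np.stack([s.shape.gt_correspondence() for s in subs])
    idx = np.linspace(0, pts.shape[1] - 1, m).astype(int)
    return ParticleSystem(pts[:, idx])


class TestHotelling:
    def test_duplicate_halves_give_t2_zero(self):
        rng = np.random.default_rng(1)
        half = rng.normal(size=(5, 16, 3))
        system = ParticleSystem(np.concatenate([half, half]))
        labels = np.array(["a"] * 5 + ["b"] * 5)
        sig = gs.hotelling_map(system, labels, "a", "b")
        assert np.allclose(sig.t2, 0.0, atol=1e-9)
        assert np.allclose(sig.p_raw, 1.0)
        assert not sig.significant.any()

    def test_permutation_null_calibration_and_fdr(self):
        """Raw p < 0.05 at ~5% under label shuffles; BH keeps the false
        discovery proportion at or under the nominal level."""
        system = jittered_null_system(n=20, m=128, seed=5)
        rng = np.random.default_rng(0)
        labels = np.array(["a"] * 10 + ["b"] * 10)
        frac, fdp = [], []
        for _ in range(50):
            lab = rng.permutation(labels)
            sig = gs.hotelling_map(system, lab, "a", "b")
            frac.append(np.mean(sig.p_raw < 0.05))
            fdp.append(float(sig.significant.any()))
        assert abs(np.mean(frac) - 0.05) <= 0.03
        assert np.mean(fdp) <= 0.05

    def test_radial_only_variation_is_conservative(self):
        """Without landmark jitter the per-point scatter is rank-1 and
        the F-based p-values are conservative, never anti-conservative."""
        spec = sc.CohortSpec(
            group_sizes={"healthy": 20, "control": 0, "tr": 0},
            noise_sd=1.0, gt_resolution=16, seed=6,
        )
        subs, _ = sc.generate_cohort(spec, with_masks=False)
        pts = np.stack([s.shape.gt_correspondence() for s in subs])
        system = ParticleSystem(pts[:, :128])
        rng = np.random.default_rng(2)
        labels = np.array(["a"] * 10 + ["b"] * 10)
        frac = [
            np.mean(gs.hotelling_map(system, rng.permutation(labels),
                                     "a", "b").p_raw < 0.05)
            for _ in range(20)
        ]
        assert np.mean(frac) <= 0.05

    def test_bulge_localizes_to_free_wall(self):
        """With a strong free-wall bulge, significant points concentrate
        on the generator's free-wall patch."""
        spec = sc.CohortSpec(
            group_sizes={"control": 12, "tr": 12},
            deformation_params=sc.DeformationParams(
                bulge_amp=5.0, apex_blunt_amp=0.0, base_width_amp=0.0,
                midwall_pinch_amp=0.0),
            noise_sd=1.0, seed=8,
        )
        subs, man = sc.generate_cohort(spec, with_masks=False)
        system = attach_ground_truth([s.shape for s in subs], m=256,
                                     center=False)
        sig = gs.hotelling_map(system, man["group"].to_numpy(),
                               "control", "tr")
        assert sig.significant.sum() > 0
        pts = system.points.mean(axis=0)
        th = np.arccos(np.clip(pts[:, 2] / np.linalg.norm(pts, axis=1),
                               -1, 1))
        ph = np.arctan2(pts[:, 1], pts[:, 0])
        on_patch = sc.free_wall_patch(th, ph)
        frac = np.mean(on_patch[sig.significant])
        assert frac >= 0.7

    def test_small_groups_rejected(self):
        system = ParticleSystem(np.zeros((3, 4, 3)))
        labels = np.array(["a", "a", "b"])
        with pytest.raises(ValueError):
            gs.hotelling_map(system, labels, "a", "b")

    def test_permutation_variant_agrees_on_strong_effect(self):
        rng = np.random.default_rng(3)
        a = rng.normal(size=(8, 16, 3))
        b = rng.normal(size=(8, 16, 3))
        b[:, :4] += 3.0  # strong shift on the first four points
        system = ParticleSystem(np.concatenate([a, b]))
        labels = np.array(["a"] * 8 + ["b"] * 8)
        par = gs.hotelling_map(system, labels, "a", "b")
        perm = gs.hotelling_map_permutation(system, labels, "a", "b",
                                            n_perm=200, seed=0)
        assert set(np.where(perm.significant)[0]) >= {0, 1, 2, 3}
        assert np.array_equal(par.t2, perm.t2)


class TestArrows:
    def test_identical_groups_zero_arrows(self):
        x = np.random.default_rng(0).normal(size=(4, 12))
        m = ShapeMatrix(np.vstack([x, x]),
                        group3=np.array(["a"] * 4 + ["b"] * 4))
        arrows, mags = gs.mean_difference_arrows(m, "a", "b")
        assert np.allclose(arrows, 0.0)

    def test_pure_translation_uniform_arrows(self):
        x = np.random.default_rng(1).normal(size=(3, 12))
        t = np.tile([1.0, -2.0, 0.5], 4)
        m = ShapeMatrix(np.vstack([x, x + t]),
                        group3=np.array(["a"] * 3 + ["b"] * 3))
        arrows, mags = gs.mean_difference_arrows(m, "a", "b")
        assert np.allclose(arrows, [1.0, -2.0, 0.5], atol=1e-9)

    def test_magnitudes_integrate_to_difference_norm(self):
        m = two_group_matrix(dim=15)
        arrows, mags = gs.mean_difference_arrows(m, "tr", "control")
        res = gs.ldv_scores(m, "tr", "control")
        assert np.isclose((mags ** 2).sum(), (res.d ** 2).sum())
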