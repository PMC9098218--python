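"""First-level contrasts, group GLM, smoothness/resels, FWE, clusters."""
import numpy as np
import pandas as pd
import pytest
from scipy import ndimage, stats

from volmmn import clusters, glm, rft
from volmmn.images import ImageGeometry
from volmmn.montage import make_montage


def _design(ns, covariate=False, seed=0):
    groups = sum(([g] * n for g, n in zip(("PLA", "AMI", "BIP"), ns)), [])
    frame = pd.DataFrame({"group": groups})
    if covariate:
        rng = np.random.default_rng(seed)
        frame["plasma_task"] = np.where(
            frame["group"] == "PLA", 0.0, rng.uniform(10, 100, len(frame))
        )
        return glm.GroupDesign.from_frame(frame)
    return glm.GroupDesign.from_frame(frame, covariate=None)


class TestFirstLevel:
    def _cells(self, base):
        return {
            ("standard", "stable"): base[0],
            ("standard", "volatile"): base[1],
            ("deviant", "stable"): base[2],
            ("deviant", "volatile"): base[3],
        }

    def test_identical_conditions_zero_mismatch(self):
        img = np.random.default_rng(0).standard_normal((4, 4, 6))
        out = glm.first_level_contrasts(self._cells([img] * 4))
        assert np.allclose(out["mismatch"], 0)
        assert np.allclose(out["interaction"], 0)

    def test_stable_only_mismatch_equals_interaction(self):
        rng = np.random.default_rng(1)
        base = rng.standard_normal((4, 4, 6))
        effect = rng.standard_normal((4, 4, 6))
        cells = self._cells([base + effect, base, base, base])
        out = glm.first_level_contrasts(cells)
        assert np.allclose(out["interaction"], out["stable_mismatch"])
        assert np.allclose(out["stable_mismatch"], effect)
        assert np.allclose(out["volatile_mismatch"], 0)

    def test_noiseless_mismatch_recovers_template(self):
        rng = np.random.default_rng(2)
        std = rng.standard_normal((4, 4, 6))
        dev = rng.standard_normal((4, 4, 6))
        out = glm.first_level_contrasts(self._cells([std, std, dev, dev]))
        assert np.allclose(out["mismatch"], std - dev)

    def test_empty_cell_flagged(self):
        stack = np.zeros((3, 2, 2, 2))
        roles = np.array(["standard", "standard", "deviant"])
        stab = np.array(["stable", "stable", "stable"])
        with pytest.raises(glm.EmptyCellError):
            glm.cell_means_from_trials(stack, roles, stab)


class TestGroupGLM:
    def test_matches_welch_t(self):
        rng = np.random.default_rng(3)
        design = _design((10, 8, 0)) if False else _design((10, 8, 2))
        Y = rng.standard_normal((20, 3, 3, 4))
        sm = glm.group_glm(
            Y, design, design.contrast({"PLA": 1.0, "AMI": -1.0}), variance_model="welch"
        )
        ref = stats.ttest_ind(Y[:10], Y[10:18], equal_var=False)
        assert np.abs(sm.t - ref.statistic).max() < 1e-10
        assert np.abs(sm.df - ref.df).max() < 1e-9

    def test_equal_group_sizes_match_pooled_t(self):
        """With equal group sizes the Welch statistic coincides with the
        classical two-sample t."""
        rng = np.random.default_rng(4)
        design = _design((9, 9, 2))
        Y = rng.standard_normal((20, 5, 5, 2))
        sm = glm.group_glm(
            Y, design, design.contrast({"PLA": 1.0, "AMI": -1.0}), variance_model="welch"
        )
        ref = stats.ttest_ind(Y[:9], Y[9:18], equal_var=True)
        assert np.abs(sm.t - ref.statistic).max() < 1e-10

    def test_self_contrast_is_zero(self):
        rng = np.random.default_rng(5)
        design = _design((6, 6, 6))
        Y = rng.standard_normal((18, 2, 2, 2))
        c = design.contrast({"PLA": 1.0}) - design.contrast({"PLA": 1.0})
        sm = glm.group_glm(Y, design, c)
        assert np.allclose(sm.t, 0)

    def test_covariate_centered_within_groups(self):
        design = _design((8, 8, 8), covariate=True)
        X, cols = design.X, design.columns
        for j, name in enumerate(cols):
            if name.startswith("plasma:"):
                g = name.split(":")[1]
                sel = design.groups == g
                assert abs(X[sel, j].sum()) < 1e-9
                assert np.all(X[~sel, j] == 0)

    def test_rank_deficient_design_rejected(self):
        frame = pd.DataFrame({"group": ["PLA"] * 4 + ["AMI"] * 4, "plasma_task": 0.0})
        design = glm.GroupDesign.from_frame(frame, covariate=None)
        bad = glm.GroupDesign(
            X=np.column_stack([design.X, design.X[:, 0]]),
            columns=design.columns + ("dup",),
            groups=design.groups,
            group_names=design.group_names,
        )
        with pytest.raises(np.linalg.LinAlgError):
            glm.group_glm(np.random.default_rng(0).standard_normal((8, 2, 2, 2)), bad, np.zeros(3))

    def test_battery_has_eight_contrasts(self):
        design = _design((4, 4, 4))
        assert len(design.battery()) == 8


class TestSmoothnessAndResels:
    def test_known_fwhm_recovered(self):
        rng = np.random.default_rng(6)
        fw = 3.0
        sig = fw / (2 * np.sqrt(2 * np.log(2)))
        res = ndimage.gaussian_filter(
            rng.standard_normal((20, 24, 24, 40)), (0, sig, sig, sig), mode="wrap"
        )
        s = rft.estimate_smoothness(res, np.ones((24, 24, 40), bool))
        for f in s.fwhm_vox:
            assert abs(f - fw) / fw < 0.15

    def test_unsmoothed_floor(self):
        rng = np.random.default_rng(7)
        res = rng.standard_normal((30, 16, 16, 20))
        s = rft.estimate_smoothness(res, np.ones((16, 16, 20), bool))
        # independent voxels: lambda = 2, FWHM = sqrt(4 ln2 / 2) ~ 1.18
        for f in s.fwhm_vox:
            assert abs(f - 1.18) < 0.15

    def test_resel_volume_additive(self):
        fw = (2.0, 2.0, 2.0)
        m1 = np.zeros((20, 10, 10), bool)
        m1[:10] = True
        m2 = np.zeros((20, 10, 10), bool)
        m2[:20] = True
        r1 = rft.resel_counts(m1, fw)
        r2 = rft.resel_counts(m2, fw)
        assert r2[3] == pytest.approx(2 * r1[3] + 9 * 9 / 8, rel=1e-6)

    def test_degenerate_residuals_rejected(self):
        res = np.ones((5, 4, 4, 4))
        res[0] = 0  # sum of squares fine, but constant field
        with pytest.raises(ValueError):
            rft.estimate_smoothness(np.zeros((5, 4, 4, 4)), np.ones((4, 4, 4), bool))


class TestPeakFWE:
    RESELS = (1.0, 10.0, 30.0, 60.0)

    def test_limits(self):
        df = np.array(20.0)
        assert rft.peak_p_fwe(np.array(40.0), df, self.RESELS) < 1e-6
        assert rft.peak_p_fwe(np.array(0.0), df, self.RESELS) == 1.0
        assert rft.peak_p_fwe(np.array(-3.0), df, self.RESELS) == 1.0

    def test_monotone_in_t(self):
        t = np.linspace(0.5, 12, 100)
        p = rft.peak_p_fwe(t, np.full_like(t, 20.0), self.RESELS)
        assert np.all(np.diff(p) <= 1e-12)

    def test_monotone_in_search_volume(self):
        halved = tuple(r / 2 for r in self.RESELS)
        t = np.linspace(2, 8, 50)
        p_full = rft.peak_p_fwe(t, np.full_like(t, 20.0), self.RESELS)
        p_half = rft.peak_p_fwe(t, np.full_like(t, 20.0), halved)
        assert np.all(p_half <= p_full + 1e-12)

    def test_corrected_never_below_uncorrected(self):
        t = np.linspace(0.1, 10, 200)
        p = rft.peak_p_fwe(t, np.full_like(t, 15.0), self.RESELS)
        assert np.all(p >= stats.t.sf(t, 15.0) - 1e-12)

    def test_critical_t_consistent(self):
        tc = rft.critical_t(0.05, 20.0, self.RESELS)
        assert rft.peak_p_fwe(np.array(tc), np.array(20.0), self.RESELS) == pytest.approx(0.05, abs=1e-4)


class TestPermutation:
    def test_min_p_is_one_over_nperm_plus_one(self):
        rng = np.random.default_rng(8)
        design = _design((6, 6, 6))
        Y = rng.standard_normal((18, 4, 4, 4))
        Y[6:12] += 50.0  # huge AMI effect
        cm = rft.permutation_maxT(Y, design, ("AMI", "BIP"), n_perm=99, seed=0)
        assert cm.p_fwe.min() == pytest.approx(1 / 100)

    def test_strong_effect_detected(self):
        rng = np.random.default_rng(9)
        design = _design((8, 8, 8))
        Y = rng.standard_normal((24, 6, 6, 6))
        Y[8:16, 2, 2, 2] += 4.0
        cm = rft.permutation_maxT(Y, design, ("AMI", "BIP"), n_perm=1000, seed=1)
        assert cm.p_fwe[2, 2, 2] <= 0.01

    def test_low_nperm_warns(self):
        rng = np.random.default_rng(10)
        design = _design((4, 4, 4))
        with pytest.warns(UserWarning, match="n_perm"):
            rft.permutation_maxT(
                rng.standard_normal((12, 2, 2, 2)), design, ("AMI", "BIP"), n_perm=50, seed=0
            )


class TestMaskAndClusters:
    def _corrected(self, sig, t=None):
        shape = sig.shape
        smap = glm.StatMap(
            t=t if t is not None else np.where(sig, 6.0, 0.0),
            df=np.full(shape, 20.0),
            contrast_name="x",
            mask=np.ones(shape, bool),
        )
        return rft.CorrectedMap(
            statmap=smap,
            p_fwe=np.where(sig, 0.01, 1.0),
            significant=sig,
            alpha=0.05,
            resels=(1, 1, 1, 1),
            method="grf",
        )

    def test_functional_mask_union(self):
        a = np.zeros((4, 4, 4), bool)
        b = np.zeros((4, 4, 4), bool)
        a[0, 0, 0] = True
        b[3, 3, 3] = True
        m = rft.build_functional_mask(self._corrected(a), self._corrected(b))
        assert m.sum() == 2 and m[0, 0, 0] and m[3, 3, 3]

    def test_empty_map_empty_table(self, montage):
        geom = ImageGeometry.reduced(montage)
        sig = np.zeros(geom.shape, bool)
        table = clusters.extract_clusters(self._corrected(sig), geom)
        assert len(table) == 0

    def test_single_voxel_cluster(self, montage):
        geom = ImageGeometry.reduced(montage)
        sig = np.zeros(geom.shape, bool)
        sig[4, 5, 6] = True
        table = clusters.extract_clusters(self._corrected(sig), geom)
        assert len(table) == 1
        row = table.iloc[0]
        assert row["k_E"] == 1
        assert row["tw_min_ms"] == row["tw_max_ms"] == geom.t_ms[6]

    def test_corner_connectivity_not_joined(self, montage):
        """Voxels touching only at a corner belong to different clusters
        under 18-connectivity."""
        geom = ImageGeometry.reduced(montage)
        sig = np.zeros(geom.shape, bool)
        sig[4, 4, 4] = True
        sig[5, 5, 5] = True
        table = clusters.extract_clusters(self._corrected(sig), geom)
        assert len(table) == 2

    def test_injected_window_recovered_at_high_snr(self, montage):
        """A strong effect injected over a known scalp-time span yields one
        cluster whose significant time window covers that span within one
        time bin."""
        geom = ImageGeometry.reduced(montage)
        rng = np.random.default_rng(11)
        design = _design((12, 12, 0)) if False else _design((12, 12, 2))
        sig = 1.5
        imgs = ndimage.gaussian_filter(
            rng.standard_normal((26,) + geom.shape), (0, sig, sig, sig), mode="constant"
        )
        imgs /= imgs.std()
        tsel = (geom.t_ms >= 100) & (geom.t_ms <= 232)
        effect = np.zeros(geom.shape)
        effect[6:10, 8:12, tsel] = 3.0
        imgs[:12] += effect  # PLA group carries the effect
        sm = glm.group_glm(imgs, design, design.contrast({"PLA": 1.0, "AMI": -1.0}))
        smooth = rft.estimate_smoothness(sm.residuals, np.ones(geom.shape, bool))
        cm = rft.fwe_peak_correct(sm, smooth)
        table = clusters.extract_clusters(cm, geom)
        assert len(table) >= 1
        top = table.iloc[0]
        dt = geom.voxel_size[2]
        assert top["tw_min_ms"] <= 100 + dt
        assert top["tw_max_ms"] >= 232 - dt

    def test_z_equivalent_matches_tail(self):
        z = clusters.z_equivalent(3.0, 30.0)
        assert stats.norm.sf(z) == pytest.approx(stats.t.sf(3.0, 30.0), rel=1e-9)
        # extreme t: finite, very large z while the tail is representable
        assert 15 < clusters.z_equivalent(60.0, 60.0) < 40
        # beyond double-precision tails the printed convention is Inf
        assert clusters.z_equivalent(500.0, 400.0) == np.inf
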