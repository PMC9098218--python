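"""ROI peak extraction, drug x sensor ANOVA, and behavioral group tests."""
import numpy as np
import pandas as pd
import pytest
from scipy import stats

from volmmn import roi


class TestDifferenceWave:
    def _epochs(self, montage, data, roles):
        from volmmn.preprocessing import Epochs

        n, c, t = data.shape
        return Epochs(
            data=data,
            times_ms=np.linspace(-100, 400, t),
            ch_names=montage.ch_names,
            metadata=pd.DataFrame({"trial": np.arange(n), "role": roles}),
            sfreq=250.0,
            rejected=np.zeros(n, bool),
            rejection_by_channel=pd.Series(0.0, index=montage.ch_names),
        )

    def test_identical_conditions_zero_difference(self, montage):
        rng = np.random.default_rng(0)
        trial = rng.standard_normal((63, 126))
        data = np.stack([trial] * 6)
        roles = np.array(["standard"] * 3 + ["deviant"] * 3)
        out = roi.difference_wave(self._epochs(montage, data, roles))
        assert np.allclose(out["difference"], 0)

    def test_average_is_sum_over_n(self, montage):
        rng = np.random.default_rng(1)
        data = rng.standard_normal((5, 63, 126))
        roles = np.array(["standard"] * 2 + ["deviant"] * 3)
        out = roi.difference_wave(self._epochs(montage, data, roles))
        np.testing.assert_allclose(out["deviant"], data[2:].sum(axis=0) / 3)

    def test_empty_condition_raises(self, montage):
        data = np.zeros((3, 63, 126))
        roles = np.array(["standard"] * 3)
        with pytest.raises(ValueError):
            roi.difference_wave(self._epochs(montage, data, roles))


class TestPeakMMN:
    def test_noiseless_trough_latency(self, montage):
        times = np.arange(-100.0, 400.1, 4.0)
        wave = -2.0 * np.exp(-0.5 * ((times - 180.0) / 30.0) ** 2)
        diff = np.tile(wave, (63, 1))
        table = roi.peak_mmn(diff, times, montage.ch_names)
        assert (table["latency_ms"] == 180.0).all()
        assert np.allclose(table["amplitude_uv"], -2.0)
        assert not table["boundary"].any()

    def test_monotone_wave_flagged_at_boundary(self, montage):
        times = np.arange(-100.0, 400.1, 4.0)
        diff = np.tile(-times / 100.0, (63, 1))
        table = roi.peak_mmn(diff, times, montage.ch_names)
        last_in_window = times[(times >= 150) & (times <= 250)][-1]
        assert (table["latency_ms"] == last_in_window).all()
        assert table["boundary"].all()

    def test_missing_channel_raises(self, montage):
        times = np.arange(-100.0, 400.1, 4.0)
        with pytest.raises(ValueError, match="missing"):
            roi.peak_mmn(np.zeros((63, times.size)), times, montage.ch_names, channels=("XX",))


def _peak_frame(rng, group_means, n_per_group=6, sd=1.0, subject_sd=None):
    """Synthetic peak table; rows are independent unless subject_sd adds a
    shared per-subject offset (the additive ANOVA assumes independence)."""
    rows = []
    for g, mu in group_means.items():
        for i in range(n_per_group):
            base = rng.normal(mu, subject_sd) if subject_sd else mu
            for ch in roi.ROI_CHANNELS:
                base = rng.normal(mu, sd) if not subject_sd else base
                rows.append(
                    {
                        "group": g,
                        "channel": ch,
                        "subject": f"{g}{i}",
                        "latency_ms": base + rng.normal(0, 0.3),
                        "amplitude_uv": rng.normal(-2, 0.3),
                    }
                )
    return pd.DataFrame(rows)


class TestAnova:
    def test_identical_groups_not_significant(self):
        rng = np.random.default_rng(2)
        frame = _peak_frame(rng, {"PLA": 170.0, "AMI": 170.0, "BIP": 170.0})
        res = roi.anova_drug_by_sensor(frame, "latency_ms")
        assert res.p_group > 0.05
        assert res.posthoc is None

    def test_matches_brute_force_sums_of_squares(self):
        """On a balanced table, the two-way ANOVA F for each factor equals
        the textbook sums-of-squares computation."""
        rng = np.random.default_rng(3)
        frame = _peak_frame(rng, {"PLA": 168.0, "AMI": 172.0, "BIP": 182.0}, n_per_group=4)
        res = roi.anova_drug_by_sensor(frame, "latency_ms")

        y = frame["latency_ms"].to_numpy()
        g = frame["group"].to_numpy()
        ch = frame["channel"].to_numpy()
        grand = y.mean()
        a_levels, b_levels = np.unique(g), np.unique(ch)
        n_a, n_b = len(a_levels), len(b_levels)
        n_rep = len(y) / (n_a * n_b)
        ss_a = n_rep * n_b * sum((y[g == a].mean() - grand) ** 2 for a in a_levels)
        ss_b = n_rep * n_a * sum((y[ch == b].mean() - grand) ** 2 for b in b_levels)
        ss_cells = n_rep * sum(
            (y[(g == a) & (ch == b)].mean() - grand) ** 2
            for a in a_levels
            for b in b_levels
        )
        ss_ab = ss_cells - ss_a - ss_b
        ss_e = sum(
            ((y[(g == a) & (ch == b)] - y[(g == a) & (ch == b)].mean()) ** 2).sum()
            for a in a_levels
            for b in b_levels
        )
        df_e = len(y) - n_a * n_b
        f_a = (ss_a / (n_a - 1)) / (ss_e / df_e)
        f_ab = (ss_ab / ((n_a - 1) * (n_b - 1))) / (ss_e / df_e)
        assert res.F_group == pytest.approx(f_a, abs=1e-10)
        assert res.F_interaction == pytest.approx(f_ab, abs=1e-10)

    def test_latency_shift_detected_with_posthoc(self):
        rng = np.random.default_rng(4)
        frame = _peak_frame(rng, {"PLA": 168.0, "AMI": 170.0, "BIP": 182.0}, n_per_group=10, sd=3.0)
        res = roi.anova_drug_by_sensor(frame, "latency_ms")
        assert res.p_group < 0.05
        assert res.posthoc is not None
        pair = res.posthoc.set_index(["a", "b"])
        key = ("PLA", "BIP") if ("PLA", "BIP") in pair.index else ("BIP", "PLA")
        assert pair.loc[key, "p"] < 0.05


class TestBehaviorStats:
    def _frame(self, rng, hit_means, rt_means, n=20):
        rows = []
        for g in hit_means:
            for i in range(n):
                rows.append(
                    {
                        "id": f"{g}{i}",
                        "group": g,
                        "hit_rate": np.clip(rng.normal(hit_means[g], 0.05), 0, 1),
                        "mean_rt": rng.normal(rt_means[g], 50),
                    }
                )
        return pd.DataFrame(rows)

    def test_identical_groups(self):
        rng = np.random.default_rng(5)
        frame = self._frame(rng, dict.fromkeys(("PLA", "AMI", "BIP"), 0.95),
                            dict.fromkeys(("PLA", "AMI", "BIP"), 500.0))
        out = roi.behavior_stats(frame)
        assert out["rt_anova"]["p"] > 0.01
        assert out["hit_kruskal"]["p"] > 0.01

    def test_group_difference_detected(self):
        rng = np.random.default_rng(6)
        frame = self._frame(
            rng,
            {"PLA": 0.90, "LEV": 0.90, "GAL": 0.99},
            {"PLA": 500.0, "LEV": 500.0, "GAL": 500.0},
            n=26,
        )
        out = roi.behavior_stats(frame)
        assert out["hit_kruskal"]["p"] < 0.05
        assert "hit_posthoc" in out

    def test_low_performer_flagged(self):
        rng = np.random.default_rng(7)
        frame = self._frame(rng, dict.fromkeys(("PLA", "AMI"), 0.95),
                            dict.fromkeys(("PLA", "AMI"), 500.0), n=5)
        frame.loc[0, "hit_rate"] = 0.4
        out = roi.behavior_stats(frame)
        assert frame.loc[0, "id"] in out["low_performers"]

    def test_kruskal_type_one_error_rate(self):
        """Under identical hit distributions the Kruskal-Wallis test rejects
        at roughly the nominal 5% rate."""
        rng = np.random.default_rng(8)
        rejections = 0
        n_sim = 300
        for _ in range(n_sim):
            frame = self._frame(rng, dict.fromkeys(("A", "B", "C"), 0.9),
                                dict.fromkeys(("A", "B", "C"), 500.0), n=15)
            if roi.behavior_stats(frame)["hit_kruskal"]["p"] < 0.05:
                rejections += 1
        assert 0.02 <= rejections / n_sim <= 0.09
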