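"""Behavioral metrics: aggregation, Gaussian stimulus coverage, group
heatmaps and the repeated-measures ANOVA."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from pointspv.metrics import (CoverageHeatmap, TrialRecord, block_metrics,
                              coverage_heatmap, fixation_heatmap,
                              method_anovas, read_trials_csv, rm_anova,
                              stimulus_coverage, write_trials_csv)


def make_trial(pid="p0", method="pointspv", correct=True, rt=5.0,
               fixations=((50.0, 50.0),), n_saccades=3, block=1, stim="s0"):
    return TrialRecord(participant_id=pid, block=block, method=method,
                       stimulus_id=stim, response=1 if correct else 0, truth=1,
                       reaction_time=rt, fixations=list(fixations),
                       n_saccades=n_saccades)


class TestTrialRecord:
    @pytest.mark.parametrize("bad", [{"reaction_time": 0.0},
                                     {"reaction_time": 31.0},
                                     {"n_saccades": -1},
                                     {"block": 3}])
    def test_invalid_records_rejected(self, bad):
        kw = dict(participant_id="p", block=1, method="canny", stimulus_id="s",
                  response=0, truth=0, reaction_time=5.0, fixations=[],
                  n_saccades=0)
        kw.update(bad)
        with pytest.raises(ValueError):
            TrialRecord(**kw)

    def test_csv_roundtrip(self, tmp_path):
        trials = [make_trial(pid=f"p{i}", rt=2.0 + i,
                             fixations=[(10.0 + i, 20.0), (30.0, 40.0)])
                  for i in range(4)]
        write_trials_csv(trials, tmp_path / "t.csv")
        back = read_trials_csv(tmp_path / "t.csv")
        assert len(back) == 4
        assert back[2].fixations == trials[2].fixations
        assert back[3].reaction_time == trials[3].reaction_time


class TestBlockMetrics:
    def test_accuracy_fraction(self):
        trials = [make_trial(correct=i < 9) for i in range(10)]
        table = block_metrics(trials, image_shape=(100, 100))
        assert table.loc[("p0", "pointspv"), "accuracy"] == pytest.approx(0.9)

    def test_mean_reaction_time(self):
        trials = [make_trial(rt=2.0), make_trial(rt=4.0)]
        table = block_metrics(trials, image_shape=(100, 100))
        assert table.loc[("p0", "pointspv"), "mean_rt"] == pytest.approx(3.0)

    def test_matches_brute_force_aggregation(self):
        """20 participants x 2 methods x 6 trials: compare against an
        independently coded dictionary-based aggregation."""
        rng = np.random.default_rng(0)
        trials = []
        for i in range(20):
            for method in ("pointspv", "canny"):
                for j in range(6):
                    trials.append(make_trial(
                        pid=f"p{i:02d}", method=method,
                        correct=bool(rng.random() < 0.8),
                        rt=float(rng.uniform(1, 20)),
                        fixations=[(float(rng.uniform(0, 99)),
                                    float(rng.uniform(0, 99)))],
                        n_saccades=int(rng.integers(0, 40)), stim=f"s{j}"))
        table = block_metrics(trials, image_shape=(100, 100))
        cells = {}
        for t in trials:
            cells.setdefault((t.participant_id, t.method), []).append(t)
        for key, ts in cells.items():
            assert table.loc[key, "accuracy"] == pytest.approx(
                sum(t.response == t.truth for t in ts) / len(ts))
            assert table.loc[key, "mean_rt"] == pytest.approx(
                sum(t.reaction_time for t in ts) / len(ts))
            assert table.loc[key, "mean_saccades"] == pytest.approx(
                sum(t.n_saccades for t in ts) / len(ts))
            assert table.loc[key, "mean_coverage"] == pytest.approx(
                sum(stimulus_coverage(t.fixations, (100, 100)) for t in ts) / len(ts))

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            block_metrics([])


class TestStimulusCoverage:
    def test_no_fixations_zero(self):
        assert stimulus_coverage([], (64, 64)) == 0.0

    def test_every_pixel_fixated_gives_full_coverage(self):
        fixations = [(y, x) for y in range(64) for x in range(64)]
        assert stimulus_coverage(fixations, (64, 64)) == pytest.approx(1.0, abs=1e-12)

    def test_central_fixation_matches_brute_force(self):
        """Double-loop oracle on a 101x101 image, sigma=50."""
        cov = stimulus_coverage([(50.0, 50.0)], (101, 101), sigma=50.0)
        total = 0.0
        for y in range(101):
            for x in range(101):
                total += np.exp(-((y - 50.0) ** 2 + (x - 50.0) ** 2) / (2 * 50.0 ** 2))
        assert cov == pytest.approx(total / 101 ** 2, abs=1e-9)

    def test_adding_fixation_never_decreases(self, rng):
        fixations = [(float(rng.uniform(0, 63)), float(rng.uniform(0, 63)))
                     for _ in range(8)]
        covs = [stimulus_coverage(fixations[:k], (64, 64)) for k in range(9)]
        assert all(b >= a for a, b in zip(covs, covs[1:]))
        assert all(0.0 <= c <= 1.0 for c in covs)

    def test_duplicate_fixation_idempotent(self):
        f = [(10.0, 20.0)]
        np.testing.assert_array_equal(coverage_heatmap(f, (64, 64)),
                                      coverage_heatmap(f + f, (64, 64)))

    def test_out_of_bounds_fixation_rejected(self):
        with pytest.raises(ValueError):
            stimulus_coverage([(70.0, 10.0)], (64, 64))


class TestFixationHeatmap:
    def test_single_participant_equals_own_heatmap(self):
        trials = [make_trial(fixations=[(10.0, 10.0), (40.0, 50.0)])]
        hm = fixation_heatmap(trials, (64, 64))
        np.testing.assert_array_equal(
            hm.values, coverage_heatmap(trials[0].fixations, (64, 64)))

    def test_disjoint_participants_average_to_half(self):
        a = make_trial(pid="a", fixations=[(10.0, 10.0)])
        b = make_trial(pid="b", fixations=[(90.0, 90.0)])
        # sigma small enough that the two regions are effectively disjoint
        hm = fixation_heatmap([a, b], (100, 100), sigma=5.0)
        assert hm.values[10, 10] == pytest.approx(0.5)
        assert hm.values[90, 90] == pytest.approx(0.5)
        assert hm.values.min() >= 0.0 and hm.values.max() <= 1.0

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            fixation_heatmap([], (64, 64))


class TestRMAnova:
    def test_identical_vectors(self):
        res = rm_anova([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.F == 0.0 and res.p == 1.0

    def test_degrees_of_freedom_twenty_participants(self, rng):
        res = rm_anova(rng.normal(size=20), rng.normal(size=20))
        assert res.df == (1, 19)

    def test_equals_squared_paired_t(self, rng):
        """Dual-route check on 20 random paired datasets: the ANOVA F
        (via the repeated-measures fit) must equal the squared paired-t
        statistic, and the p-values must agree."""
        for _ in range(20):
            n = int(rng.integers(5, 30))
            a = rng.normal(size=n)
            b = a + rng.normal(size=n) * 0.5 + 0.2
            res = rm_anova(a, b)
            t = stats.ttest_rel(a, b)
            assert res.F == pytest.approx(t.statistic ** 2, rel=1e-9)
            assert res.p == pytest.approx(t.pvalue, rel=1e-6)
            assert res.F >= 0

    def test_unpaired_lengths_rejected(self, rng):
        with pytest.raises(ValueError):
            rm_anova(rng.normal(size=5), rng.normal(size=6))


class TestMethodAnovas:
    def test_per_metric_table_with_holm(self, rng):
        trials = []
        for i in range(10):
            for method, boost in (("pointspv", 0.9), ("canny", 0.7)):
                for j in range(5):
                    trials.append(make_trial(
                        pid=f"p{i}", method=method,
                        correct=bool(rng.random() < boost),
                        rt=float(rng.uniform(2, 10) + (0 if method == "pointspv" else 2)),
                        fixations=[(float(rng.uniform(0, 99)),) * 2],
                        n_saccades=int(rng.integers(5, 30))))
        table = block_metrics(trials, image_shape=(100, 100))
        anova = method_anovas(table, holm=True)
        assert set(anova.index) == {"accuracy", "mean_rt", "mean_saccades",
                                    "mean_coverage"}
        assert (anova["p_holm"] >= anova["p"] - 1e-12).all()
        assert (anova["df1"] == 1).all() and (anova["df2"] == 9).all()
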