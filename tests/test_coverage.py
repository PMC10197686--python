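import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gcdecay.coverage import (CoverageSet, compare_classes, coverage_stats,
                              detect_start, normalize_profile,
                              select_gene_classes, select_major_isoform,
                              trajectory_beta, window_log2fc, window_mean)


class TestDetectStart:
    def test_step_profile(self):
        assert detect_start([0, 0, 0, 1, 1, 1], threshold=0.15) == 4

    def test_linear_ramp_crossing(self):
        # ramp 0..1 over 100 positions: value at position k is (k-1)/99;
        # first value > 0.15 is at k=16
        ramp = np.linspace(0, 1, 100)
        assert detect_start(ramp, threshold=0.15) == 16

    def test_flat_profile_undetectable(self):
        assert detect_start([3.0, 3.0, 3.0]) is None
        assert detect_start([0.0, 0.0]) is None

    @pytest.mark.parametrize("threshold", [0.05, 0.15, 0.30])
    def test_matches_linear_scan_oracle(self, threshold):
        rng = np.random.default_rng(7)
        for _ in range(300):
            v = rng.poisson(rng.uniform(0, 8), size=rng.integers(5, 60))
            got = detect_start(v, threshold=threshold)
            if v.max() == v.min():
                assert got is None
                continue
            norm = (v - v.min()) / (v.max() - v.min())
            expected = next((i + 1 for i, x in enumerate(norm)
                             if x > threshold), None)
            assert got == expected

    def test_scale_invariance(self):
        rng = np.random.default_rng(3)
        v = rng.poisson(5, size=80).astype(float)
        for c in (0.5, 3.0, 1000.0):
            assert detect_start(v) == detect_start(v * c)
            n1, n2 = normalize_profile(v), normalize_profile(v * c)
            assert np.allclose(n1, n2)


class TestWindows:
    def test_identical_profiles_give_zero_l2fc(self):
        assert window_log2fc(0.4, 0.4, floor=0.01) == 0.0

    def test_doubled_mean_gives_one(self):
        assert window_log2fc(0.8, 0.4, floor=0.01) == pytest.approx(1.0)

    def test_zero_control_guarded_by_floor(self):
        val = window_log2fc(0.4, 0.0, floor=0.01)
        assert np.isfinite(val) and val > 0

    def test_window_clipping(self):
        v = np.arange(10.0)
        assert window_mean(v, center=1, half_window=4) == \
            pytest.approx(np.mean(v[:5]))


class TestTrajectoryBeta:
    def test_closed_form_no_intercept(self):
        # sum(x*y)/sum(x*x) with x = 0..4 and y = (0,.5,1,1.5,2) is 15/30
        vals = [0.0, 0.5, 1.0, 1.5, 2.0]
        assert trajectory_beta(vals, mode="regression",
                               intercept=False) == pytest.approx(0.5)

    def test_constant_series_zero_slope(self):
        assert trajectory_beta([2.0] * 5, mode="regression") == \
            pytest.approx(0.0)

    def test_difference_mode(self):
        assert trajectory_beta([120.0, 100.0], mode="difference") == -20.0

    def test_difference_needs_two_values(self):
        with pytest.raises(ValueError):
            trajectory_beta([1.0, 2.0, 3.0], mode="difference")

    def test_regression_needs_three(self):
        with pytest.raises(ValueError):
            trajectory_beta([1.0, 2.0], mode="regression")

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.floats(-10, 10), min_size=3, max_size=12))
    def test_agrees_with_polyfit(self, vals):
        got = trajectory_beta(vals, mode="regression", intercept=True)
        expected = np.polyfit(np.arange(len(vals)), vals, 1)[0]
        assert got == pytest.approx(expected, abs=1e-8)


def _toy_covset():
    """Two conditions x one timepoint, two transcripts of one gene each."""
    def prof(onset, length=400, depth=30):
        x = np.zeros(length)
        x[onset - 1:] = depth
        return x

    tracks = {
        "cov_control_t8": {"tA": prof(50), "tB": prof(60)},
        "cov_treated_t8": {"tA": prof(40), "tB": prof(80)},
    }
    samples = pd.DataFrame({
        "sample": ["cov_control_t8", "cov_treated_t8"],
        "condition": ["control", "treated"], "timepoint": [8.0, 8.0]})
    return CoverageSet(tracks=tracks, samples=samples,
                       tx2gene={"tA": "gA", "tB": "gB"})


class TestCoverageStats:
    def test_difference_mode_start_deltas(self):
        stats = coverage_stats(_toy_covset(), mode="difference", window=100)
        s = stats.set_index("transcript_id")
        assert s.loc["tA", "beta_start"] == -10   # earlier start under treatment
        assert s.loc["tB", "beta_start"] == 20
        assert s.loc["tA", "beta_cov"] > 0
        assert s.loc["tB", "beta_cov"] < 0

    def test_zero_erosion_start_identical(self, sim_small):
        from gcdecay.simulate import SimConfig, simulate_coverage

        cfg = SimConfig(n_genes=30, seed=9, decay_erosion_rate=0.0)
        from gcdecay.simulate import simulate_annotation
        ann, truth = simulate_annotation(cfg)
        cov = simulate_coverage(cfg, ann, truth, noise=False)
        for tid in cov.transcript_ids[:10]:
            starts = {detect_start(cov.get(s, tid))
                      for s in cov.tracks}
            assert len(starts) == 1

    def test_noiseless_ramp_crossing_closed_form(self):
        from gcdecay.simulate import SimConfig, simulate_annotation, \
            simulate_coverage

        cfg = SimConfig(n_genes=5, seed=4, ramp_len=50)
        ann, truth = simulate_annotation(cfg)
        cov = simulate_coverage(cfg, ann, truth, noise=False)
        # ramp value k/ramp_len first exceeds 0.15 at k = 8
        k = int(np.floor(0.15 * cfg.ramp_len)) + 1
        for rec in ann.records:
            onset = int(truth.cov_start[("control", 4.0)].iloc[
                int(rec.gene_id[1:])])
            got = detect_start(cov.get("cov_control_t4", rec.transcript_id))
            assert got == onset + k - 1

    def test_three_prime_end_machinery_runs(self):
        stats = coverage_stats(_toy_covset(), mode="difference",
                               window=100, end="three")
        assert len(stats) == 2


class TestMajorIsoform:
    def _covset(self, totals, lengths):
        tracks = {"s1": {tid: np.full(n, t / n)
                         for (tid, t), n in zip(totals.items(),
                                                lengths.values())}}
        samples = pd.DataFrame({"sample": ["s1"], "condition": ["control"],
                                "timepoint": [0.0]})
        return CoverageSet(tracks=tracks, samples=samples,
                           tx2gene={tid: "g1" for tid in totals})

    def test_highest_total_wins(self):
        cov = self._covset({"tA": 1000.0, "tB": 400.0},
                           {"tA": 100, "tB": 100})
        best, _ = select_major_isoform(cov)
        assert best == {"g1": "tA"}

    def test_tie_broken_by_length(self):
        cov = self._covset({"tA": 500.0, "tB": 500.0},
                           {"tA": 900, "tB": 1200})
        best, _ = select_major_isoform(cov)
        assert best == {"g1": "tB"}

    def test_zero_coverage_gene_reported(self):
        cov = self._covset({"tA": 0.0}, {"tA": 100})
        best, zero = select_major_isoform(cov)
        assert best == {} and zero == ["g1"]


def test_class_test_directionality_over_seeds():
    """The planted stabilized/degraded coverage signature is detected in
    the correct direction in >= 95% of 20 seeded simulations."""
    from gcdecay.simulate import SimConfig, simulate_all

    ok = 0
    n_rep = 20
    for rep in range(n_rep):
        cfg = SimConfig(n_genes=100, seed=1000 + rep)
        sim = simulate_all(cfg, coverage=True, slam=False)
        truth = sim.truth.genes.set_index("gene_id")
        classes = truth["class_label"].map(
            {"TE_down": "stabilized", "TE_up": "degraded", "NS": "control"})
        stats5 = coverage_stats(sim.coverage)
        out = compare_classes(stats5, classes).set_index(
            ["statistic", "group"])
        ok += int(out.loc[("beta_cov", "stabilized"), "pvalue"] < 0.05
                  and out.loc[("beta_cov", "degraded"), "pvalue"] < 0.05
                  and out.loc[("beta_start", "stabilized"), "pvalue"] < 0.05)
    assert ok >= int(0.95 * n_rep), f"directionality in {ok}/{n_rep}"


class TestClassSelectionAndComparison:
    def test_select_gene_classes_counts(self):
        rng = np.random.default_rng(0)
        n = 400
        diff = pd.DataFrame({
            "rna_pvalue": rng.uniform(size=n),
            "rna_l2fc": rng.normal(size=n),
        }, index=[f"g{i}" for i in range(n)])
        tpm = pd.Series(10.0, index=diff.index)
        labels = select_gene_classes(diff, tpm, n_top=30, n_control=100,
                                     rng=1)
        vc = labels.value_counts()
        assert vc["stabilized"] == 30 and vc["degraded"] == 30
        assert vc["control"] == 100
        # classes are disjoint by construction of a single label series
        assert labels.index.is_unique

    def test_compare_classes_skips_empty(self):
        stats = pd.DataFrame({"gene_id": ["g1", "g2"],
                              "beta_cov": [0.1, 0.2],
                              "beta_start": [-1.0, 0.5]})
        classes = pd.Series({"g1": "control", "g2": "control"})
        out = compare_classes(stats, classes)
        assert (out["status"] == "skipped").all()

    def test_bedgraph_round_trip(self, tmp_path):
        cov = _toy_covset()
        cov.to_bedgraph_dir(tmp_path)
        back = CoverageSet.from_bedgraph_dir(tmp_path)
        for s in cov.tracks:
            for tid in cov.tracks[s]:
                assert np.allclose(cov.get(s, tid), back.get(s, tid))
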