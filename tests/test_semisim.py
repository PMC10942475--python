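import numpy as np
import pandas as pd
import pytest
from scipy.stats import chisquare

from motifdiff.core_io import count_overlaps
from motifdiff.semisim import (
    BiasSpec,
    BindingScenario,
    apply_composition_bias,
    build_plan,
    builtin_scenario,
    downsample_fragments,
    effective_fraction,
    quantile_match_fold_changes,
    simulate_two_group_dataset,
)

from conftest import make_fragments


class TestQuantileMatch:
    def test_identity_mapping(self):
        s = BindingScenario("s", [1.0, 4.0, 9.0], [-0.5, -1.0, -2.0])
        out = quantile_match_fold_changes(np.array([1.0, 4.0, 9.0]), s)
        assert out.tolist() == [-0.5, -1.0, -2.0]

    def test_single_reference(self):
        s = BindingScenario("s", [5.0], [-1.5])
        out = quantile_match_fold_changes(np.array([0.1, 100.0]), s)
        assert out.tolist() == [-1.5, -1.5]

    def test_interpolated_map_with_tie_rule(self):
        s = BindingScenario("s", [0.0, 10.0], [-0.1, -2.0])
        out = quantile_match_fold_changes(np.array([1.0, 5.0, 9.0]), s)
        # quantile map -> (0, 5, 10); 5 is equidistant -> lower index -> -0.1
        assert out.tolist() == [-0.1, -0.1, -2.0]

    def test_empty_target(self):
        s = builtin_scenario("activation")
        assert len(quantile_match_fold_changes(np.array([]), s)) == 0


class TestEffectiveFraction:
    def test_log_scale_reading(self):
        frac, group = effective_fraction(-2.0, 0.5)
        assert frac == pytest.approx(0.5)
        assert group == "B"

    def test_strength_zero_is_identity(self):
        frac, _ = effective_fraction(-3.7, 0.0)
        assert frac == 1.0

    def test_zero_lfc(self):
        frac, group = effective_fraction(0.0, 2.0)
        assert frac == 1.0 and group == "A"

    def test_negative_strength_rejected(self):
        with pytest.raises(ValueError):
            effective_fraction(1.0, -0.1)


def _plan_for(peaks, log2fc, p):
    df = peaks.copy()
    df["enrichment"] = 1.0
    scenario = BindingScenario("fixed", np.arange(len(df), dtype=float), np.asarray(log2fc))
    plan = build_plan(df, scenario, p)
    # force the exact fold-changes (bypass quantile matching) for unit control
    plan.peaks["log2fc"] = np.asarray(log2fc, dtype=float)
    frac, group = effective_fraction(plan.peaks["log2fc"].to_numpy(), p)
    plan.peaks["fraction"], plan.peaks["group"] = frac, group
    return plan


class TestDownsample:
    peaks = pd.DataFrame({"chrom": ["c"], "start": [0], "end": [1000]})

    def _frags(self, n, sample="s1"):
        return make_fragments([("c", 10 * i, 10 * i + 50) for i in range(n)], sample)

    def test_formula_half(self):
        plan = _plan_for(self.peaks, [-1.0], p=1.0)  # fraction 0.5
        out = downsample_fragments(self._frags(10), plan, "B", seed=1)
        assert len(out) == 5
        assert plan.realized["s1"]["ns"][0] == 5

    def test_fraction_one_identity(self):
        plan = _plan_for(self.peaks, [-1.0], p=0.0)
        fs = self._frags(10)
        out = downsample_fragments(fs, plan, "B", seed=1)
        pd.testing.assert_frame_equal(out.df, fs.df)

    def test_ceiling_keeps_all(self):
        plan = _plan_for(self.peaks, [-0.152], p=1.0)  # fraction ~0.9 -> ceil(2.7)=3
        out = downsample_fragments(self._frags(3), plan, "B", seed=1)
        assert len(out) == 3

    def test_seed_required(self):
        plan = _plan_for(self.peaks, [-1.0], p=1.0)
        with pytest.raises(ValueError):
            downsample_fragments(self._frags(4), plan, "B", seed=None)

    def test_same_seed_identical_different_seed_same_counts(self):
        plan = _plan_for(self.peaks, [-1.0], p=1.0)
        a = downsample_fragments(self._frags(20), plan, "B", seed=5)
        b = downsample_fragments(self._frags(20), plan, "B", seed=5)
        c = downsample_fragments(self._frags(20), plan, "B", seed=6)
        pd.testing.assert_frame_equal(a.df, b.df)
        assert len(c) == len(a)
        assert not a.df.equals(c.df)

    def test_other_group_untouched(self):
        plan = _plan_for(self.peaks, [-1.0], p=1.0)  # group B downsampled
        fs = self._frags(10)
        out = downsample_fragments(fs, plan, "A", seed=1)
        assert len(out) == 10

    def test_counts_never_increase(self):
        rng = np.random.default_rng(0)
        peaks = pd.DataFrame(
            {"chrom": "c", "start": [0, 2000], "end": [1000, 2500]}
        )
        plan = _plan_for(peaks, [-1.5, -0.3], p=1.0)
        starts = rng.integers(0, 3000, 300)
        fs = make_fragments([("c", s, s + 80) for s in starts])
        out = downsample_fragments(fs, plan, "B", seed=2)
        before = count_overlaps([fs], peaks)
        after = count_overlaps([out], peaks)
        assert (after <= before).all()

    def test_overlap_assignment_largest_then_lower_index(self):
        # fragment [90,210) overlaps peak0 [0,100) by 10 and peak1 [100,300) by 110
        peaks = pd.DataFrame({"chrom": ["c", "c"], "start": [0, 100], "end": [100, 300]})
        plan = _plan_for(peaks, [-10.0, 0.0], p=1.0)  # peak0 kills, peak1 keeps
        fs = make_fragments([("c", 90, 210)])
        out = downsample_fragments(fs, plan, "B", seed=0)
        assert len(out) == 1  # assigned to peak1 (larger overlap), not removed


class TestCompositionBias:
    def test_identity_target(self):
        fs = make_fragments([("c", 0, 60)] * 50 + [("c", 0, 200)] * 50)
        bias = BiasSpec("fragment_length", [0.5, 0.5, 0.0, 0.0])
        out = apply_composition_bias(fs, bias, seed=0)
        assert len(out) == 100

    def test_degenerate_target_only_nf(self):
        fs = make_fragments([("c", 0, 60)] * 30 + [("c", 0, 200)] * 30)
        bias = BiasSpec("fragment_length", [1.0, 0.0, 0.0, 0.0])
        out = apply_composition_bias(fs, bias, seed=0)
        assert (out.lengths <= 120).all() and len(out) == 30

    def test_gc_ratio_of_densities(self):
        n = 40_000
        rng = np.random.default_rng(1)
        gc = rng.uniform(0, 1, n)
        fs = make_fragments([("c", i, i + 50) for i in range(n)], gc=gc)
        bias = BiasSpec("gc", [0.75, 0.25], bin_edges=[0.0, 0.5, 1.0])
        out = apply_composition_bias(fs, bias, seed=2)
        low = (out.df["gc"] < 0.5).sum()
        high = (out.df["gc"] >= 0.5).sum()
        assert low / high == pytest.approx(3.0, rel=0.1)

    def test_target_histogram_reached(self):
        n = 20_000
        rng = np.random.default_rng(3)
        fs = make_fragments(
            [("c", i, i + int(L)) for i, L in
             enumerate(rng.choice([60, 200, 400, 600], n, p=[0.4, 0.3, 0.2, 0.1]))]
        )
        target = np.array([0.25, 0.25, 0.25, 0.25])
        out = apply_composition_bias(fs, BiasSpec("fragment_length", target), seed=4)
        from motifdiff.core_io import classify_fragments

        labels = classify_fragments(out)
        obs = np.array([(labels == c).sum() for c in ("NF", "mono", "di", "multi")])
        stat, p = chisquare(obs, target * obs.sum())
        assert p > 0.01

    def test_unreachable_mass_warns(self):
        fs = make_fragments([("c", 0, 60)] * 10)  # NF only
        with pytest.warns(UserWarning):
            apply_composition_bias(fs, BiasSpec("fragment_length", [0.5, 0.5, 0, 0]), seed=0)


class TestSimulateTwoGroups:
    def _baseline(self, n_samples=6, n_frags=200, seed=0):
        rng = np.random.default_rng(seed)
        out = []
        for j in range(n_samples):
            starts = rng.integers(0, 5000, n_frags)
            out.append(
                make_fragments([("c", s, s + 100) for s in starts], f"s{j}")
            )
        return out

    chip = pd.DataFrame(
        {"chrom": ["c"], "start": [1000], "end": [2000], "enrichment": [10.0]}
    )

    def test_strength_zero_identity(self):
        baseline = self._baseline()
        res = simulate_two_group_dataset(
            baseline, self.chip, builtin_scenario("activation"), 0.0, seed=1
        )
        for orig, sim in zip(baseline, res.group_a + res.group_b):
            pd.testing.assert_frame_equal(orig.df, sim.df)

    def test_monotone_in_strength(self):
        baseline = self._baseline()
        kept = {}
        for p in (1.0, 3.0):
            res = simulate_two_group_dataset(
                baseline, self.chip, builtin_scenario("activation"), p, seed=1
            )
            kept[p] = sum(len(fs) for fs in res.group_b)
        assert kept[3.0] <= kept[1.0]

    def test_six_samples_split_three_three(self):
        res = simulate_two_group_dataset(
            self._baseline(6), self.chip, builtin_scenario("activation"), 1.0, seed=1
        )
        assert len(res.group_a) == 3 and len(res.group_b) == 3

    def test_realized_log_ratio_matches_planted_effect(self):
        # large counts: realized B-vs-A log2 ratio approaches -p*|log2FC|
        baseline = self._baseline(n_samples=4, n_frags=6000, seed=5)
        chip = pd.DataFrame(
            {"chrom": ["c"], "start": [0], "end": [6000], "enrichment": [5.0]}
        )
        scenario = BindingScenario("fixed", [5.0], [-1.0])
        res = simulate_two_group_dataset(baseline, chip, scenario, 1.0, seed=2)
        n_a = np.mean([count_overlaps([fs], chip)[0, 0] for fs in res.group_a])
        n_b = np.mean([count_overlaps([fs], chip)[0, 0] for fs in res.group_b])
        assert np.log2(n_b / n_a) == pytest.approx(-1.0, abs=0.1)

    def test_truth_manifest_contents(self):
        res = simulate_two_group_dataset(
            self._baseline(), self.chip, builtin_scenario("activation"), 1.0, seed=9
        )
        assert res.manifest["seed"] == 9
        assert res.manifest["scenario"] == "activation"
        assert res.manifest["n_chip_peaks"] == 1
        assert not res.manifest["zero_perturbed_fragments"]


class TestScenarios:
    def test_builtin_shapes(self):
        act = builtin_scenario("activation")
        hap = builtin_scenario("haploinsufficiency")
        # activation hits high-occupancy peaks hardest; haploinsufficiency the opposite
        assert abs(act.log2fc[-1]) > abs(act.log2fc[0])
        assert abs(hap.log2fc[0]) > abs(hap.log2fc[-1])
        assert np.abs(act.log2fc).max() > np.abs(hap.log2fc).max()

    def test_tsv_round_trip(self, tmp_path):
        from motifdiff.semisim import read_scenario_tsv, write_scenario_tsv

        s = builtin_scenario("activation", n_ref=50)
        p = tmp_path / "s.tsv"
        write_scenario_tsv(s, p)
        back = read_scenario_tsv(p, "activation")
        assert np.allclose(back.enrichment, s.enrichment)
        assert np.allclose(back.log2fc, s.log2fc)
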