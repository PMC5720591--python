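"""Gating: control-derived thresholds, G1 peak finding, phase taxonomy."""

import warnings

import numpy as np
import pytest

from mcmflow import (
    EventTable,
    GatingConfig,
    NoiseModel,
    Thresholds,
    classify_phases,
    derive_thresholds,
    find_g1_peak,
    model_hesc,
    phase_fractions,
    simulate_negative_control,
    simulate_sample,
    split_s_by_mcm,
    summarize_channel_by_phase,
)
from mcmflow.gating import EXCLUDED, G1_MCM_POS, MCM_NEG, S_MCM_POS, compare_phase_summaries
from mcmflow.simdata import cyclin_e_pair
from conftest import make_events


def sorted_order_statistic(values, q):
    """Brute-force linear-interpolation quantile from the sorted sample."""
    v = np.sort(np.asarray(values, dtype=float))
    pos = q * (v.size - 1)
    lo = int(np.floor(pos))
    hi = min(lo + 1, v.size - 1)
    return v[lo] + (pos - lo) * (v[hi] - v[lo])


class TestThresholds:
    def test_degenerate_control(self):
        control = make_events(mcm=[5.0] * 600, edu=[5.0] * 600)
        control.metadata["is_negative_control"] = True
        thr = derive_thresholds(control)
        assert thr.mcm == 5.0
        assert thr.edu == 5.0

    def test_quantile_equals_brute_force_order_statistic(self):
        rng = np.random.default_rng(31)
        values = rng.lognormal(np.log(10), 0.3, size=5000)
        control = make_events(mcm=values, edu=values[::-1])
        control.metadata["is_negative_control"] = True
        thr = derive_thresholds(control, GatingConfig(control_quantile=0.995))
        assert thr.mcm == pytest.approx(sorted_order_statistic(values, 0.995), rel=1e-12)

    def test_monotone_in_control_quantile(self):
        rng = np.random.default_rng(32)
        values = rng.lognormal(np.log(10), 0.4, size=2000)
        control = make_events(mcm=values, edu=values)
        control.metadata["is_negative_control"] = True
        thrs = [
            derive_thresholds(control, GatingConfig(control_quantile=q)).mcm
            for q in (0.9, 0.95, 0.99, 0.995)
        ]
        assert thrs == sorted(thrs)

    def test_false_positive_rate_below_half_percent(self, hesc_sample, hesc_calls):
        # cells with truly zero loaded MCM should almost never be called MCM+
        sample, _ = hesc_sample
        truly_negative = (sample.truth["mcm"] == 0).to_numpy() & ~sample.truth["is_doublet"].to_numpy()
        called_pos = sample.events.channel("mcm") > hesc_calls.thresholds.mcm
        fp = (called_pos & truly_negative).sum() / truly_negative.sum()
        assert fp < 0.005

    def test_empty_control_rejected(self):
        control = make_events(mcm=[], edu=[])
        control.metadata["is_negative_control"] = True
        with pytest.raises(ValueError):
            derive_thresholds(control)

    def test_contaminated_control_warns(self):
        rng = np.random.default_rng(33)
        bg = rng.lognormal(np.log(10), 0.2, 3000)
        stained = rng.lognormal(np.log(300), 0.2, 1500)
        mixed = np.concatenate([bg, stained])
        control = make_events(mcm=mixed, edu=np.full_like(mixed, 10.0))
        control.metadata["is_negative_control"] = True
        with pytest.warns(UserWarning, match="bimodal"):
            derive_thresholds(control)


class TestG1Peak:
    def test_known_mixture(self):
        rng = np.random.default_rng(34)
        dna = np.concatenate([
            rng.normal(100, 5, 6000),   # G1
            rng.normal(200, 8, 2000),   # G2/M
            rng.uniform(100, 200, 2000),  # S
        ])
        assert find_g1_peak(dna) == pytest.approx(100, abs=2)

    def test_point_mass(self):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            assert find_g1_peak(np.full(50, 42.0)) == 42.0

    def test_simulated_peak_near_g1_level(self, hesc_sample):
        sample, _ = hesc_sample
        peak = find_g1_peak(sample.events.channel("dna_a"))
        assert peak == pytest.approx(model_hesc().dna_g1_level, rel=0.03)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            find_g1_peak(np.array([]))


class TestClassify:
    thr = Thresholds(edu=10.0, mcm=10.0)

    def classify(self, **channels):
        events = make_events(**channels)
        return classify_phases(events, self.thr, g1_peak=100.0)

    def test_rule_application(self):
        calls = self.classify(
            dna_a=[100.0, 100.0, 100.0, 150.0, 200.0],
            edu=[0.0, 50.0, 0.0, 50.0, 0.0],
            mcm=[20.0, 20.0, 5.0, 20.0, 5.0],
        )
        assert list(calls.label) == [G1_MCM_POS, S_MCM_POS, MCM_NEG, S_MCM_POS, MCM_NEG]
        assert list(calls.is_early_s) == [False, True, False, False, False]

    def test_anomalies_fold_into_mcm_neg(self):
        # EdU-negative, MCM-positive, non-G1 DNA: counted, classed MCM-negative
        calls = self.classify(dna_a=[200.0, 100.0], edu=[0.0, 50.0], mcm=[50.0, 5.0])
        assert list(calls.label) == [MCM_NEG, MCM_NEG]
        assert calls.counts["anomalous_mcm_pos_non_g1"] == 1
        assert calls.counts["anomalous_edu_pos_mcm_neg"] == 1

    def test_partition_property(self, hesc_calls):
        labels = set(hesc_calls.label.unique())
        assert labels <= {G1_MCM_POS, S_MCM_POS, MCM_NEG, EXCLUDED}
        non_excluded = (hesc_calls.label != EXCLUDED).sum()
        by_class = sum((hesc_calls.label == lab).sum() for lab in (G1_MCM_POS, S_MCM_POS, MCM_NEG))
        assert by_class == non_excluded

    def test_noiseless_labels_match_generative_truth(self):
        model = model_hesc()
        noiseless = NoiseModel.noiseless()
        sample = simulate_sample(model, noiseless, 20000, seed=41)
        control = simulate_negative_control(model, noiseless, 5000, seed=42)
        calls = classify_phases(sample.events, derive_thresholds(control))
        truth = sample.truth
        expected = np.where(
            (truth["edu"] > 0) & (truth["mcm"] > 0), S_MCM_POS,
            np.where((truth["phase"] == "G1") & (truth["mcm"] > 0), G1_MCM_POS, MCM_NEG),
        )
        keep = (calls.label != EXCLUDED).to_numpy()
        agreement = (calls.label.to_numpy()[keep] == expected[keep]).mean()
        assert agreement >= 0.99

    def test_doublets_excluded_by_singlet_gate(self, hesc_model):
        noise = NoiseModel(doublet_fraction=0.05)
        sample = simulate_sample(hesc_model, noise, 20000, seed=43)
        control = simulate_negative_control(hesc_model, noise, 5000, seed=44)
        calls = classify_phases(sample.events, derive_thresholds(control))
        doublet = sample.truth["is_doublet"].to_numpy()
        excluded = calls.mask(EXCLUDED)
        assert (excluded & doublet).sum() / doublet.sum() > 0.8
        assert (excluded & ~doublet).sum() / (~doublet).sum() < 0.1

    def test_affine_invariance_of_labels(self, hesc_sample):
        sample, control = hesc_sample
        calls = classify_phases(sample.events, derive_thresholds(control))

        def transform(table):
            df = table.data.copy()
            for ch in ("edu", "mcm"):
                df[ch] = 3.0 * df[ch] + 7.0
            df["dna_a"] = 3.0 * df["dna_a"]  # DNA windows are relative to the peak
            df["dna_h"] = 3.0 * df["dna_h"]
            return EventTable(df, metadata=dict(table.metadata))

        calls2 = classify_phases(transform(sample.events), derive_thresholds(transform(control)))
        assert (calls.label == calls2.label).all()


class TestPhaseFractions:
    def test_hand_labelled(self):
        calls = classify_phases(
            make_events(dna_a=[100, 100, 100, 100], edu=[0, 0, 50, 0], mcm=[20, 20, 20, 5]),
            Thresholds(10.0, 10.0), g1_peak=100.0,
        )
        fractions = phase_fractions(calls)
        assert fractions[G1_MCM_POS] == 0.5
        assert fractions[S_MCM_POS] == 0.25
        assert fractions[MCM_NEG] == 0.25

    def test_fractions_sum_to_one(self, hesc_calls):
        fractions = phase_fractions(hesc_calls)
        total = fractions[G1_MCM_POS] + fractions[S_MCM_POS] + fractions[MCM_NEG]
        assert total == pytest.approx(1.0)

    def test_g1_share_matches_analytic_occupancy(self, hesc_calls):
        # hESC-like: G1 occupies 2*(1 - exp(-alpha*T_G1)) of the population
        model = model_hesc()
        expected = 2 * (1 - np.exp(-model.alpha * model.g1_hours))
        n = hesc_calls.n_non_excluded
        se = np.sqrt(expected * (1 - expected) / n)
        assert abs(hesc_calls.is_g1.mean() - expected) < 3 * se + 0.01

    def test_all_excluded_rejected(self):
        calls = classify_phases(
            make_events(dna_a=[100.0], edu=[0.0], mcm=[20.0],
                        fsc_a=[1.0], ssc_a=[1.0]),
            Thresholds(10.0, 10.0),
            GatingConfig(scatter_gate={"fsc_a": (10.0, 100.0)}),
            g1_peak=100.0,
        )
        with pytest.raises(ValueError):
            phase_fractions(calls)


class TestSplitS:
    @pytest.fixture(scope="class")
    def cyclin_e_batch(self):
        control_model, perturbed_model = cyclin_e_pair()
        noise = NoiseModel()
        from mcmflow import simulate_mixture

        control = simulate_sample(control_model, noise, 20000, seed=51)
        perturbed = simulate_mixture(
            [(perturbed_model, 0.7), (control_model, 0.3)], noise, 20000, seed=52
        )
        neg = simulate_negative_control(control_model, noise, 10000, seed=53)
        thr = derive_thresholds(neg)
        control_calls = classify_phases(control.events, thr)
        perturbed_calls = classify_phases(perturbed.events, thr)
        return control, control_calls, perturbed, perturbed_calls

    def test_boundary_is_reference_order_statistic(self, cyclin_e_batch):
        control, control_calls, _, _ = cyclin_e_batch
        split = split_s_by_mcm(control.events, control_calls, control.events, control_calls)
        ref = control.events.channel("mcm")[control_calls.is_early_s.to_numpy()]
        assert split.boundary == pytest.approx(sorted_order_statistic(ref, 0.10), rel=1e-12)

    def test_control_calibrates_to_quantile(self, cyclin_e_batch):
        control, control_calls, _, _ = cyclin_e_batch
        split = split_s_by_mcm(control.events, control_calls, control.events, control_calls)
        assert split.fraction_low_early_s == pytest.approx(0.10, abs=0.02)

    def test_underlicensed_population_detected(self, cyclin_e_batch):
        control, control_calls, perturbed, perturbed_calls = cyclin_e_batch
        split = split_s_by_mcm(
            perturbed.events, perturbed_calls, control.events, control_calls
        )
        assert split.fraction_low_early_s > 0.5  # majority of early-S cells underlicensed
        assert split.s_mcm_class.isin(["high", "low", "n/a"]).all()

    def test_all_above_boundary(self):
        thr = Thresholds(10.0, 10.0)
        events = make_events(dna_a=[100.0] * 20, edu=[50.0] * 20, mcm=np.linspace(100, 200, 20))
        calls = classify_phases(events, thr, g1_peak=100.0)
        split = split_s_by_mcm(events, calls, events, calls)
        assert split.fraction_low_all_s <= 0.10 + 1e-9

    def test_reference_without_early_s_rejected(self):
        thr = Thresholds(10.0, 10.0)
        events = make_events(dna_a=[100.0] * 20, edu=[50.0] * 20, mcm=[100.0] * 20)
        ref = make_events(dna_a=[200.0] * 20, edu=[0.0] * 20, mcm=[5.0] * 20)
        calls = classify_phases(events, thr, g1_peak=100.0)
        ref_calls = classify_phases(ref, thr, g1_peak=100.0)
        with pytest.raises(ValueError, match="early-S"):
            split_s_by_mcm(events, calls, ref, ref_calls)


class TestSummaries:
    def test_mean_and_median(self):
        events = make_events(dna_a=[100.0] * 3, edu=[0.0] * 3, mcm=[20.0] * 3,
                             cdt1=[1.0, 2.0, 3.0])
        calls = classify_phases(events, Thresholds(10.0, 10.0), g1_peak=100.0)
        assert summarize_channel_by_phase(events, calls, "cdt1", "mean")[G1_MCM_POS] == 2.0
        assert summarize_channel_by_phase(events, calls, "cdt1", "median")[G1_MCM_POS] == 2.0

    def test_fold_change_between_scaled_samples(self):
        model = model_hesc()
        noise = NoiseModel()
        folds = []
        for seed in (61, 62):
            a = simulate_sample(model, noise, 10000, seed=seed)
            b = simulate_sample(model, noise, 10000, seed=seed + 10)
            b.events.data["cdt1"] = 1.0 * b.events.channel("mcm")
            a.events.data["cdt1"] = 2.0 * a.events.channel("mcm")
            neg = simulate_negative_control(model, noise, 5000, seed=seed + 20)
            thr = derive_thresholds(neg)
            sa = summarize_channel_by_phase(a.events, classify_phases(a.events, thr), "cdt1")
            sb = summarize_channel_by_phase(b.events, classify_phases(b.events, thr), "cdt1")
            folds.append((sa[G1_MCM_POS], sb[G1_MCM_POS]))
        fold, p = compare_phase_summaries([f[0] for f in folds], [f[1] for f in folds])
        assert fold == pytest.approx(2.0, rel=0.1)

    def test_ttest_needs_two_replicates(self):
        with pytest.raises(ValueError, match=">=2"):
            compare_phase_summaries([5.0], [1.0])

    def test_empty_subset_is_nan_with_warning(self):
        events = make_events(dna_a=[100.0], edu=[0.0], mcm=[20.0], cdt1=[1.0])
        calls = classify_phases(events, Thresholds(10.0, 10.0), g1_peak=100.0)
        with pytest.warns(UserWarning, match="no cells"):
            out = summarize_channel_by_phase(events, calls, "cdt1")
        assert np.isnan(out[S_MCM_POS])
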