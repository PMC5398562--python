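"""Statistics layer: trimmed R/non-R, fraction estimation, classification,
normalisation, profiling, replicate aggregation, histograms."""

import math
from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from replicyto.errors import ParameterError, ProfileError
from replicyto.population import (
    params_for_ratio,
    preset,
    sample_population,
    with_seed,
)
from replicyto.stats import (
    cell_cycle_profile,
    classify_replicating,
    compare_conditions,
    estimate_labelled_fraction,
    normalize_protein_signal,
    r_non_r_ratio,
    signal_histogram,
    signal_intensity,
    trim_counts,
)


def oracle_r_non_r(signals, f):
    """Independent brute-force oracle: full stable sort, slice, mean."""
    x = list(signals)
    n = len(x)
    n_r = max(1, math.floor(round((f - 0.1) * n, 9)))
    n_nonr = max(1, math.floor(round((0.9 - f) * n, 9)))
    order = sorted(range(n), key=lambda i: (-x[i], i))
    top = [x[i] for i in order[:n_r]]
    bottom = [x[i] for i in order[n - n_nonr:]]
    return sum(top) / len(top), sum(bottom) / len(bottom)


class TestRNonRRatio:
    def test_hand_computable_fixture(self, bimodal_signals):
        res = r_non_r_ratio(bimodal_signals, f=0.44)
        assert res.n_r == 34
        assert res.n_nonr == 46
        assert res.r_mean == 10.0
        assert res.nonr_mean == 1.0
        assert res.ratio == 10.0

    def test_constant_vector_gives_unity(self):
        res = r_non_r_ratio(np.full(100, 3.5), f=0.3)
        assert res.ratio == 1.0

    def test_zero_nonr_mean_reported_as_infinity(self):
        x = np.concatenate([np.full(40, 5.0), np.zeros(60)])
        res = r_non_r_ratio(x, f=0.4)
        assert math.isinf(res.ratio) and res.infinite

    def test_domain_errors(self):
        x = np.arange(100, dtype=float)
        with pytest.raises(ParameterError):
            r_non_r_ratio(x, f=0.1)
        with pytest.raises(ParameterError):
            r_non_r_ratio(x, f=0.95)
        with pytest.raises(ParameterError):
            r_non_r_ratio(np.ones(4), f=0.44)
        with pytest.raises(ParameterError):
            r_non_r_ratio(-x, f=0.44)

    @given(
        x=hnp.arrays(np.float64, st.integers(5, 400),
                     elements=st.floats(0, 1e6, allow_nan=False)),
        f=st.floats(0.11, 0.89),
    )
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_matches_brute_force_oracle(self, x, f):
        res = r_non_r_ratio(x, f)
        r_mean, nonr_mean = oracle_r_non_r(x, f)
        assert res.r_mean == pytest.approx(r_mean, rel=1e-12)
        assert res.nonr_mean == pytest.approx(nonr_mean, rel=1e-12)

    @given(
        x=hnp.arrays(np.float64, st.integers(5, 200),
                     elements=st.floats(0.01, 1e4)),
        f=st.floats(0.11, 0.89),
        c=st.floats(0.001, 1e3),
    )
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_scale_invariance(self, x, f, c):
        assert r_non_r_ratio(c * x, f).ratio == pytest.approx(
            r_non_r_ratio(x, f).ratio, rel=1e-9
        )

    def test_additive_constant_pulls_ratio_toward_one(self, bimodal_signals):
        base = r_non_r_ratio(bimodal_signals, 0.44).ratio
        shifted = r_non_r_ratio(bimodal_signals + 5.0, 0.44).ratio
        assert 1.0 < shifted < base

    def test_trim_counts_float_guard(self):
        # (0.9 - 0.44) * 100 is 45.999...986 in binary; must count as 46
        assert trim_counts(100, 0.44) == (34, 46)
        assert trim_counts(5, 0.44) == (1, 2)


class TestSignalIntensity:
    def test_equals_r_mean_of_fixture(self, bimodal_signals):
        assert signal_intensity(bimodal_signals, 0.44) == 10.0

    def test_constant_vector_returns_value(self):
        assert signal_intensity(np.full(60, 7.0), 0.44) == 7.0

    def test_appending_low_values_leaves_top_mean_unchanged(self, bimodal_signals):
        base = signal_intensity(bimodal_signals, 0.44)
        # appending nuclei below the current top set leaves the R mean alone
        # as long as the trim count floor((f-0.1)N) does not grow past it
        extended = np.concatenate([bimodal_signals, np.full(2, 0.5)])
        assert signal_intensity(extended, 0.44) == base


class TestEstimateLabelledFraction:
    def test_counting_oracle_recovers_044(self):
        rng = np.random.default_rng(5)
        x = np.concatenate([
            rng.normal(10.0, 0.5, 4400).clip(0.1),
            rng.normal(1.0, 0.1, 5600).clip(0.01),
        ])
        for method in ("gmm2", "otsu"):
            est = estimate_labelled_fraction(x, method=method)
            assert est.fraction == pytest.approx(0.44, abs=0.01)
            assert not est.low_separation

    def test_two_value_vector_exact(self):
        x = np.concatenate([np.full(30, 100.0), np.full(70, 1.0)])
        est = estimate_labelled_fraction(x)
        assert est.fraction == 0.30

    def test_weak_separation_is_flagged(self):
        params, _ = preset("edu_5min")
        pop = sample_population(with_seed(replace(params, n_cells=5000), 3))
        sig = (pop.specific_signal + pop.background_signal).to_numpy()
        est = estimate_labelled_fraction(sig)
        assert est.low_separation

    def test_minimum_sample_size(self):
        with pytest.raises(ParameterError):
            estimate_labelled_fraction(np.ones(10))


class TestClassifyReplicating:
    def test_separable_preset_flagged_separable(self):
        params, eff = preset("brdu_5min")
        pop = sample_population(with_seed(replace(params, n_cells=5000), 8))
        sig = (pop.specific_signal + pop.background_signal).to_numpy()
        _, report = classify_replicating(sig)
        assert report.separable
        assert report.ratio == pytest.approx(4.0, rel=0.25)

    def test_weak_preset_flagged_non_separable(self):
        params, eff = preset("edu_5min")
        pop = sample_population(with_seed(replace(params, n_cells=5000), 8))
        sig = (pop.specific_signal + pop.background_signal).to_numpy()
        _, report = classify_replicating(sig)
        assert not report.separable

    def test_all_background_population_is_not_separable(self):
        rng = np.random.default_rng(11)
        x = rng.lognormal(math.log(100), 0.35, 2000)
        _, report = classify_replicating(x)
        assert not report.separable
        assert report.low_separation  # unimodal input flagged unreliable
        # with a threshold above the background range: near-zero positives
        positive, report2 = classify_replicating(x, threshold=float(x.max()) + 1)
        assert positive.sum() == 0
        assert not report2.separable

    def test_user_threshold_respected(self, bimodal_signals):
        positive, report = classify_replicating(
            np.tile(bimodal_signals, 1), threshold=5.0, f=0.44
        )
        assert positive.sum() == 34
        assert report.threshold == 5.0


class TestNormalizeProteinSignal:
    def test_sixty_percent(self):
        assert normalize_protein_signal([60.0] * 5, [100.0] * 5) == 60.0

    def test_identical_is_100(self, rng):
        x = rng.lognormal(4, 0.3, 100)
        assert normalize_protein_signal(x, x) == pytest.approx(100.0)

    def test_zero_control_raises(self):
        with pytest.raises(ParameterError):
            normalize_protein_signal([1.0], [0.0, 0.0])

    def test_fucci_preset_recovers_retention(self):
        from replicyto.population import apply_protocol

        params, eff = preset("fucci_hcl20")
        pop = sample_population(with_seed(replace(params, n_cells=5000), 4))
        treated = apply_protocol(pop, eff)
        green = normalize_protein_signal(
            treated["protein_green"], pop["protein_green"]
        )
        orange = normalize_protein_signal(
            treated["protein_orange"], pop["protein_orange"]
        )
        assert green == pytest.approx(60.0, abs=0.5)
        assert orange == pytest.approx(45.0, abs=0.5)


class TestCellCycleProfile:
    def test_hand_partition(self):
        dna = np.concatenate([np.full(500, 1.0), np.full(300, 2.0),
                              np.full(200, 1.5)])
        label = np.concatenate([np.zeros(800), np.full(200, 100.0)])
        prof = cell_cycle_profile(dna, label, threshold=10.0)
        assert prof.frac_g1 == 0.5
        assert prof.frac_s == 0.2
        assert prof.frac_g2m == 0.3
        assert prof.frac_g1 + prof.frac_s + prof.frac_g2m == 1.0

    def test_all_labelled_gives_pure_s_with_warning(self):
        dna = np.linspace(1.0, 2.0, 300)
        label = np.full(300, 50.0)
        prof = cell_cycle_profile(dna, label, threshold=1.0)
        assert prof.frac_s == 1.0
        assert prof.warning is not None

    def test_single_dna_mode_raises_profile_error_with_histogram(self):
        dna = np.full(300, 1.0)
        label = np.concatenate([np.zeros(200), np.full(100, 50.0)])
        with pytest.raises(ProfileError) as err:
            cell_cycle_profile(dna, label, threshold=10.0)
        assert err.value.counts is not None

    def test_exact_recovery_on_noise_free_events(self):
        from replicyto.population import sample_flow_events

        from replicyto.params import PopulationParams, lognormal_logmean

        params = PopulationParams(
            n_cells=2000, dna_cv=0.0, seed=19,
            signal_logmean_labelled=lognormal_logmean(10_000.0, 0.1),
            signal_logsd_labelled=0.1,
            background_logmean=lognormal_logmean(10.0, 0.1),
            background_logsd=0.1,
        )
        pop = sample_population(params)
        ev = sample_flow_events(pop, acq_cv=0.0)
        # an exact label gate between the two ground-truth populations makes
        # the DNA gating itself exactly recoverable on noise-free events
        lab = pop.labelled.to_numpy()
        sig = ev.label.to_numpy()
        thr = 0.5 * (sig[~lab].max() + sig[lab].min())
        prof = cell_cycle_profile(ev.dna.to_numpy(), sig, threshold=thr)
        truth = pop.phase.value_counts(normalize=True)
        assert prof.frac_s == truth["S"]
        assert prof.frac_g1 == truth["G1"]
        assert prof.frac_g2m == truth["G2M"]


class TestCompareConditions:
    def test_identical_replicates_have_zero_sd(self, bimodal_signals):
        out = compare_conditions({"c": [bimodal_signals] * 3}, f=0.44)
        assert out[0].mean == 10.0
        assert out[0].sd == 0.0
        assert out[0].n_replicates == 3

    def test_hand_arithmetic_mean_and_sd(self):
        def vec(v):  # ratio of this fixture is exactly v
            return np.concatenate([np.full(34, float(v)), np.full(66, 1.0)])

        out = compare_conditions({"c": [vec(4), vec(5), vec(6)]}, f=0.44)
        assert out[0].ratios == (4.0, 5.0, 6.0)
        assert out[0].mean == 5.0
        assert out[0].sd == 1.0

    def test_empty_condition_rejected(self):
        with pytest.raises(ParameterError):
            compare_conditions({"c": []}, f=0.44)

    def test_seeded_replicates_have_sampling_scale_sd(self):
        params, eff = preset("brdu_30min")
        reps = []
        for s in range(3):
            pop = sample_population(with_seed(replace(params, n_cells=5000), 50 + s))
            reps.append((pop.specific_signal + pop.background_signal).to_numpy())
        out = compare_conditions({"brdu": reps}, f=0.44)
        assert out[0].mean == pytest.approx(6.0, rel=0.1)
        assert 0.0 < out[0].sd < 0.5  # replicate scatter is sampling noise only


class TestSignalHistogram:
    def test_counts_conserved_and_constant_input_single_bin(self, rng):
        x = rng.lognormal(3, 0.5, 500)
        hist = signal_histogram(x, 32)
        assert hist["count"].sum() == 500
        const = signal_histogram(np.full(50, 2.0), 10)
        assert (const["count"] > 0).sum() == 1

    def test_bimodal_preset_shows_two_modes(self):
        from scipy.ndimage import gaussian_filter1d
        from scipy.signal import find_peaks

        params, _ = preset("brdu_30min")
        pop = sample_population(with_seed(replace(params, n_cells=10_000), 31))
        sig = np.log1p((pop.specific_signal + pop.background_signal).to_numpy())
        hist = signal_histogram(sig, 64)
        smoothed = gaussian_filter1d(hist["count"].to_numpy().astype(float), 2)
        peaks, props = find_peaks(smoothed, prominence=smoothed.max() * 0.05)
        assert len(peaks) >= 2
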