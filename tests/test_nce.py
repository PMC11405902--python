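"""Collision-energy optimization: extraction, depth-5 selection, Welch gain."""

import math

import numpy as np
import pytest
from scipy import stats

from prmkit.chem import LabeledPeptide, fragment_ions, precursor_mz
from prmkit.io import TargetRecord
from prmkit.nce import (
    DEFAULT_NCE_GRID,
    NceScanSet,
    TransitionResponse,
    depth_replicate_intensities,
    extract_transition_responses,
    optimize_nce,
    quantify_nce_gain,
    select_optimal_nce,
    summarize_nce_optima,
)
from prmkit.sim import (
    NoiseModel,
    random_fragmentation_model,
    random_peptide,
    simulate_nce_scan,
)
from prmkit.spectra import CentroidSpectrum


def _target(sequence="RIAESLPVV", charge=2):
    pep = LabeledPeptide(sequence)
    return TargetRecord(pep, charge, precursor_mz(pep, charge), isolation_halfwidth=0.35)


def _scan_set_with_peaks(target, peaks_by_nce):
    """Build a scan set with one replicate per NCE from explicit peak lists."""
    spectra = {}
    for i, (nce, peaks) in enumerate(peaks_by_nce.items()):
        mzs = sorted(peaks)
        spectra[nce] = [
            CentroidSpectrum(
                i, i * 0.01, 2, np.array(mzs), np.array([peaks[m] for m in mzs]),
                precursor_mz=target.precursor_mz, isolation_halfwidth=0.35, nce=nce,
            )
        ]
    return NceScanSet(target, spectra, grid=sorted(peaks_by_nce))


class TestExtraction:
    def test_peak_inside_12ppm_window_matched(self):
        target = _target()
        frags = [f for f in fragment_ions(target.peptide, (1,)) if f.annotation == "y4+"]
        assert frags[0].mz == pytest.approx(427.29150, abs=1e-5)
        ss = _scan_set_with_peaks(target, {20.0: {427.2910: 1000.0}})
        (resp,) = [
            r for r in extract_transition_responses(ss, frags) if not r.is_precursor
        ]
        assert resp.replicates[20.0][0] == 1000.0

    def test_peak_outside_window_gives_zero(self):
        target = _target()
        frags = [f for f in fragment_ions(target.peptide, (1,)) if f.annotation == "y4+"]
        ss = _scan_set_with_peaks(target, {20.0: {427.3000: 1000.0}})
        (resp,) = [
            r for r in extract_transition_responses(ss, frags) if not r.is_precursor
        ]
        assert resp.replicates[20.0][0] == 0.0

    def test_two_peaks_in_window_summed(self):
        target = _target()
        frags = [f for f in fragment_ions(target.peptide, (1,)) if f.annotation == "y4+"]
        ss = _scan_set_with_peaks(
            target, {20.0: {427.29140: 600.0, 427.29160: 400.0}}
        )
        (resp,) = [
            r for r in extract_transition_responses(ss, frags) if not r.is_precursor
        ]
        assert resp.replicates[20.0][0] == 1000.0

    def test_short_fragments_flagged_and_precursor_traced(self):
        target = _target()
        frags = fragment_ions(target.peptide, (1,), min_length=1)
        ss = _scan_set_with_peaks(target, {20.0: {target.precursor_mz: 5000.0}})
        responses = extract_transition_responses(ss, frags)
        short = [r for r in responses if r.excluded_short]
        assert short and all(not r.eligible for r in short)
        prec = [r for r in responses if r.is_precursor]
        assert len(prec) == 1 and prec[0].replicates[20.0][0] == 5000.0

    def test_empty_scan_set_rejected(self):
        target = _target()
        with pytest.raises(ValueError):
            NceScanSet(target, {}, grid=[20.0])


def _responses_from_means(means_by_nce):
    """TransitionResponse list from {nce: [mean1, mean2, ...]} (1 replicate)."""
    n_trans = len(next(iter(means_by_nce.values())))
    out = []
    for i in range(n_trans):
        reps = {nce: np.array([means[i]]) for nce, means in means_by_nce.items()}
        out.append(TransitionResponse(f"t{i}", 300.0 + i, reps))
    return out


class TestSelection:
    def test_depth5_prefers_flat_profile_over_spiky(self):
        responses = _responses_from_means(
            {20.0: [100, 90, 80, 70, 60, 50], 30.0: [200, 150, 40, 30, 20, 10]}
        )
        optimum, table, _ = select_optimal_nce(responses, depth=5)
        scores = dict(zip(table["nce"], table["score"]))
        assert scores[20.0] == 60 and scores[30.0] == 20
        assert optimum == 20.0

    def test_all_identical_ties_to_30(self):
        means = [100, 90, 80, 70, 60, 50]
        responses = _responses_from_means({nce: means for nce in DEFAULT_NCE_GRID})
        optimum, _, _ = select_optimal_nce(responses, depth=5)
        assert optimum == 30.0

    def test_tie_off_30_breaks_to_lower(self):
        means = [100, 90, 80, 70, 60, 50]
        responses = _responses_from_means({24.0: means, 36.0: means, 30.0: [0] * 6})
        optimum, _, _ = select_optimal_nce(responses, depth=5)
        assert optimum == 24.0  # both 6 away from 30; lower wins

    def test_score_invariant_to_transition_order(self, rng):
        means_by_nce = {
            nce: list(rng.uniform(0, 100, size=8)) for nce in (10.0, 20.0, 30.0)
        }
        responses = _responses_from_means(means_by_nce)
        opt1, t1, _ = select_optimal_nce(responses, depth=5)
        shuffled = list(responses)[::-1]
        opt2, t2, _ = select_optimal_nce(shuffled, depth=5)
        assert opt1 == opt2
        assert np.allclose(t1["score"], t2["score"])

    def test_removing_below_depth_transition_keeps_optimum(self, rng):
        means_by_nce = {
            nce: sorted(rng.uniform(10, 100, size=8), reverse=True)
            for nce in (10.0, 20.0, 30.0)
        }
        responses = _responses_from_means(means_by_nce)
        opt_full, _, _ = select_optimal_nce(responses, depth=5)
        # transition "t7" holds the lowest mean at every NCE (rank 8 > depth)
        trimmed = [r for r in responses if r.annotation != "t7"]
        opt_trim, _, _ = select_optimal_nce(trimmed, depth=5)
        assert opt_full == opt_trim

    def test_fewer_than_depth_everywhere_sets_warning(self):
        responses = _responses_from_means({20.0: [10, 5], 30.0: [8, 2]})
        optimum, _, warning = select_optimal_nce(responses, depth=5)
        assert warning and optimum in (20.0, 30.0)


class TestWelchGain:
    def test_clear_gain_passes_both_gates(self):
        gain = quantify_nce_gain([400, 420, 380, 400], [100, 110, 90, 100])
        assert gain.fold_change == pytest.approx(4.0)
        assert gain.p_value < 0.01
        assert gain.improved

    def test_identical_groups_give_half(self):
        gain = quantify_nce_gain([100, 110, 90, 100], [100, 110, 90, 100])
        assert gain.p_value == 0.5
        assert not gain.improved

    def test_large_fold_without_significance_not_improved(self):
        # 2 high-variance replicates per group: fold >= 1.5 but p >> 0.05
        gain = quantify_nce_gain([300, 100], [150, 50])
        assert gain.fold_change >= 1.5
        assert gain.p_value >= 0.05
        assert not gain.improved

    def test_significant_but_small_fold_not_improved(self):
        gain = quantify_nce_gain([140, 141, 139, 140], [100, 101, 99, 100])
        assert gain.p_value < 0.001
        assert gain.fold_change < 1.5
        assert not gain.improved  # both gates required

    def test_zero_variance_degenerate_conventions(self):
        equal = quantify_nce_gain([100, 100], [100, 100])
        assert equal.p_value == 0.5 and equal.degenerate
        up = quantify_nce_gain([200, 200], [100, 100])
        assert up.p_value == 0.0 and up.degenerate and up.improved
        down = quantify_nce_gain([50, 50], [100, 100])
        assert down.p_value == 1.0 and not down.improved

    def test_single_replicate_rejected(self):
        with pytest.raises(ValueError):
            quantify_nce_gain([100], [100, 110])

    def test_p_matches_reference_t_distribution(self, rng):
        """Welch p agrees with scipy's independent implementation to 1e-9."""
        for _ in range(1000):
            nx, ny = rng.integers(2, 8, size=2)
            x = rng.normal(100, rng.uniform(1, 30), size=nx)
            y = rng.normal(rng.uniform(50, 150), rng.uniform(1, 30), size=ny)
            gain = quantify_nce_gain(x, y)
            ref = stats.ttest_ind(x, y, equal_var=False, alternative="greater")
            assert gain.p_value == pytest.approx(ref.pvalue, abs=1e-9)


class TestEndToEnd:
    def test_noiseless_scan_recovers_model_optimum_exactly(self, rng):
        pep = LabeledPeptide("DLQPETTDLY")
        target = _target("DLQPETTDLY")
        frags = fragment_ions(pep, (1, 2), min_length=1)
        model = random_fragmentation_model(
            frags, rng, precursor_mz_value=target.precursor_mz
        )
        run, truth = simulate_nce_scan(
            pep, 2, model, frags, noise=NoiseModel(cv=0.0, baseline=0.0), seed=1
        )
        assert len(run) == 80  # 20 grid values x 4 replicates
        scan_set = NceScanSet.from_run(run, target)
        result = optimize_nce(scan_set, frags)
        assert result.optimal_nce == truth["true_optimal_nce"]

    def test_seeded_injected_optimum_recovered(self):
        """A fragment response centered at 14% yields optimum 14."""
        rng = np.random.default_rng(123)
        pep = LabeledPeptide("RIAESLPVV")
        target = _target()
        frags = fragment_ions(pep, (1,), min_length=1)
        eligible = [f for f in frags if f.length >= 3]
        model_frags = {
            f.annotation: (1e5, 14.0, 6.0) for f in eligible[:8]
        }
        from prmkit.sim import FragmentationModel

        model = FragmentationModel(model_frags, precursor_midpoint=14.0)
        run, truth = simulate_nce_scan(
            pep, 2, model, frags, noise=NoiseModel(cv=0.1), seed=11
        )
        scan_set = NceScanSet.from_run(run, target)
        result = optimize_nce(scan_set, frags)
        assert truth["true_optimal_nce"] == 14.0
        assert result.optimal_nce == 14.0


class TestSummary:
    def _results(self, optima, sequences=None, improved=None):
        out = []
        for i, opt in enumerate(optima):
            seq = (sequences or ["RIAESLPVV"] * len(optima))[i]
            target = _target(seq)
            gain = quantify_nce_gain([200.0, 210.0], [100.0, 105.0])
            gain.improved = (improved or [False] * len(optima))[i]
            from prmkit.nce import NceOptimizationResult
            import pandas as pd

            out.append(
                NceOptimizationResult(
                    target, opt, gain, np.zeros(2), np.zeros(2),
                    pd.DataFrame(), [],
                )
            )
        return out

    def test_fraction_in_band(self):
        summary = summarize_nce_optima(self._results([14, 22, 26, 30, 34]))
        assert summary["fraction_in_band"] == pytest.approx(0.6)

    def test_all_at_30_gives_one(self):
        summary = summarize_nce_optima(self._results([30, 30, 30]))
        assert summary["fraction_in_band"] == 1.0

    def test_empty_class_reports_nan_not_zero(self):
        # all sequences tryptic (end K/R): nontryptic fraction undefined
        summary = summarize_nce_optima(
            self._results([20, 30], sequences=["AGSK", "AGSR"])
        )
        assert math.isnan(summary["improved_fraction_nontryptic"])
        assert summary["improved_fraction_tryptic"] == 0.0

    def test_histogram_counts_sum_to_input(self):
        summary = summarize_nce_optima(self._results([14, 14, 22, 30]))
        assert sum(summary["histogram"].values()) == 4
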